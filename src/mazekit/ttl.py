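"""Binary TTL encoding of maze events onto virtual digital-output banks.

Zone entries and exits are announced to the acquisition system as a binary
word on a digital-output board so the recording system can timestamp them.
The bit layout is fixed so every port of the engine decodes identically:

======  ==========================================================
line    meaning
======  ==========================================================
0-5     zone number 1-32, big-endian (line 0 is the most
        significant of the 6 data bits)
6       direction flag: 1 = entry, 0 = exit
7       strobe, pulsed high for one engine tick per event
======  ==========================================================

Two virtual banks emulate the physical output boards: a 48-line LED/event
bank (lines 0-31 drive the cue LEDs, 32-39 carry the zone-event word) and a
16-line valve bank (lines 0-15, one per solenoid pinch valve).
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "TTLWord",
    "OutputBank",
    "LineChange",
    "encode_zone_event",
    "decode_zone_event",
    "make_led_event_bank",
    "make_valve_bank",
    "set_led",
    "pulse_valve",
    "ZONE_WORD_WIDTH",
]

ZONE_WORD_WIDTH = 8
_DATA_BITS = 6
_FLAG_LINE = 6
_STROBE_LINE = 7

# Line blocks within the 48-line LED/event bank.
LED_LINE_BASE = 0  # lines 0-31: cue LEDs 1-32
ZONE_WORD_BASE = 32  # lines 32-39: zone-event word


@dataclass(frozen=True)
class TTLWord:
    """An ordered bit pattern on a fixed-width group of output lines."""

    bits: tuple[int, ...]
    meaning: str = "zone_code"

    def __post_init__(self) -> None:
        if any(b not in (0, 1) for b in self.bits):
            raise ValueError("bits must be 0/1")

    @property
    def width(self) -> int:
        return len(self.bits)

    def as_string(self) -> str:
        """Bit string in line order (line 0 first)."""
        return "".join(str(b) for b in self.bits)

    @classmethod
    def from_string(cls, s: str, meaning: str = "zone_code") -> "TTLWord":
        return cls(bits=tuple(int(c) for c in s), meaning=meaning)


def encode_zone_event(zone_id: int, direction: str) -> TTLWord:
    """Encode a zone entry/exit as an 8-bit TTL word (layout in module docs)."""
    if not (1 <= zone_id <= 32):
        raise ValueError(f"zone_id must be 1-32, got {zone_id}")
    if direction not in ("entry", "exit"):
        raise ValueError(f"direction must be 'entry' or 'exit', got {direction!r}")
    data = tuple((zone_id >> (_DATA_BITS - 1 - i)) & 1 for i in range(_DATA_BITS))
    flag = 1 if direction == "entry" else 0
    return TTLWord(bits=data + (flag, 1), meaning="zone_code")


def decode_zone_event(word: TTLWord) -> tuple[int, str]:
    """Inverse of :func:`encode_zone_event`; rejects out-of-range codes."""
    if word.width != ZONE_WORD_WIDTH:
        raise ValueError(f"zone words are {ZONE_WORD_WIDTH} bits, got {word.width}")
    zone_id = 0
    for b in word.bits[:_DATA_BITS]:
        zone_id = (zone_id << 1) | b
    if not (1 <= zone_id <= 32):
        raise ValueError(f"decoded zone id {zone_id} outside 1-32")
    direction = "entry" if word.bits[_FLAG_LINE] else "exit"
    return zone_id, direction


@dataclass(frozen=True)
class LineChange:
    """One timestamped level change on a bank line."""

    t: float
    bank: str
    line: int
    level: int


@dataclass
class OutputBank:
    """A virtual digital-output board: named, fixed-width, with a change log.

    Bank state is a pure function of the ordered change list; `changes`
    is append-only and replaying it from all-zero reproduces `line_state`.
    """

    name: str
    width: int
    line_state: list[int] = field(default_factory=list)
    changes: list[LineChange] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.line_state:
            self.line_state = [0] * self.width
        if len(self.line_state) != self.width:
            raise ValueError("line_state length must equal bank width")

    def write_line(self, t: float, line: int, level: int) -> bool:
        """Set one line; returns True and logs a change iff the level changed."""
        if not (0 <= line < self.width):
            raise ValueError(f"line {line} outside bank '{self.name}' width {self.width}")
        level = 1 if level else 0
        if self.line_state[line] == level:
            return False
        self.line_state[line] = level
        self.changes.append(LineChange(t=t, bank=self.name, line=line, level=level))
        return True


def make_led_event_bank() -> OutputBank:
    return OutputBank(name="led_event_bank_48", width=48)


def make_valve_bank() -> OutputBank:
    return OutputBank(name="valve_bank_16", width=16)


def set_led(bank: OutputBank, led_index: int, on: bool, t: float = 0.0):
    """Drive cue LED ``led_index`` (1-32) on the LED/event bank.

    Returns ``(bank, event_kind_or_None)``: an event kind ``"led_on"`` /
    ``"led_off"`` exactly when the line level actually changed, ``None`` for
    idempotent writes (only changes to LED status are recorded).
    """
    if not (1 <= led_index <= 32):
        raise ValueError(f"led_index must be 1-32, got {led_index}")
    changed = bank.write_line(t, LED_LINE_BASE + led_index - 1, 1 if on else 0)
    if not changed:
        return bank, None
    return bank, ("led_on" if on else "led_off")


def pulse_valve(
    bank: OutputBank,
    valve_index: int,
    open_duration: float,
    t0: float = 0.0,
    n_valves: int = 8,
) -> list[LineChange]:
    """Open then close one solenoid valve line; returns the two line changes.

    ``n_valves`` is the number of valves physically wired (default 8); indices
    beyond it are rejected even though the bank has 16 lines.
    """
    if not (1 <= valve_index <= n_valves):
        raise ValueError(f"valve_index must be 1-{n_valves}, got {valve_index}")
    if open_duration <= 0:
        raise ValueError(f"open_duration must be > 0, got {open_duration}")
    line = valve_index - 1
    bank.write_line(t0, line, 1)
    bank.write_line(t0 + open_duration, line, 0)
    return bank.changes[-2:]
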