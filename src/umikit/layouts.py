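"""Adapter layouts and UMI-locator schemes.

A *UMI locator* is a short pre-defined sequence adjacent to (or interleaved
with) the random UMI bases.  Because the locator sits at a fixed frame,
any insertion or deletion in or around the UMI shifts the locator out of
register and is caught as a locator mismatch, so indel-bearing reads can be
discarded instead of polluting the UMI space.

Two layouts are supported:

* RNA-seq: each mate starts with a 5-nt UMI, a 3-nt locator drawn from a
  small fixed set, and the ligation thymidine, i.e. a 9-nt prefix; the
  combined UMI is the concatenation of both mates' UMIs (10 nt).
* small RNA-seq: the insert is flanked by two 15-nt blocks interleaving
  three 3-nt random stretches with two 3-nt locators
  (e.g. ``NNNCGANNNTACNNN``); the combined UMI is 18 nt.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class LocatorScheme:
    """A locator pattern over {A,C,G,T,U,N}.

    ``N`` marks UMI (wildcard) positions; all other letters are fixed
    locator bases and are the only positions at which mismatches are
    counted.  ``U`` is treated as ``T`` (adapters may be specified as RNA).
    """

    pattern: str
    max_mismatches: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        pat = self.pattern.upper().replace("U", "T")
        if not pat or any(c not in "ACGTN" for c in pat):
            raise ValueError(f"invalid locator pattern {self.pattern!r}")
        object.__setattr__(self, "pattern", pat)
        if not 0 <= self.max_mismatches <= len(self.fixed_positions):
            raise ValueError(
                "max_mismatches must be between 0 and the number of "
                f"non-N positions ({len(self.fixed_positions)})"
            )

    def __len__(self) -> int:
        return len(self.pattern)

    @property
    def umi_positions(self) -> tuple[int, ...]:
        return tuple(i for i, c in enumerate(self.pattern) if c == "N")

    @property
    def fixed_positions(self) -> tuple[int, ...]:
        return tuple(i for i, c in enumerate(self.pattern) if c != "N")

    def mismatches(self, window: str) -> int:
        """Mismatch count at the fixed (non-N) positions only."""
        if len(window) != len(self.pattern):
            raise ValueError(
                f"window length {len(window)} != pattern length {len(self.pattern)}"
            )
        w = window.upper()
        return sum(1 for i in self.fixed_positions if w[i] != self.pattern[i])

    def extract_umi(self, window: str) -> str:
        """Bases at the N positions, 5'→3'."""
        if len(window) != len(self.pattern):
            raise ValueError("window length != pattern length")
        return "".join(window[i] for i in self.umi_positions)


def match_locator(window: str, scheme: LocatorScheme) -> tuple[int, bool]:
    """Compare ``window`` against a locator scheme.

    Returns ``(mismatch_count, accepted)`` where mismatches are counted at
    non-N positions only and the window is accepted iff the count does not
    exceed ``scheme.max_mismatches``.
    """
    mm = scheme.mismatches(window)
    return mm, mm <= scheme.max_mismatches


@dataclass(frozen=True)
class RnaSeqLayout:
    """Paired-end RNA-seq read layout: UMI(5) + locator(3) + ligation T + insert."""

    umi_length: int = 5
    locator_length: int = 3
    allowed_locators: frozenset[str] = frozenset({"GGG", "TCA", "ATC"})
    ligation_base_length: int = 1

    @property
    def trim_length(self) -> int:
        return self.umi_length + self.locator_length + self.ligation_base_length

    @property
    def combined_umi_length(self) -> int:
        return 2 * self.umi_length

    @property
    def umi_space_size(self) -> int:
        """Number of distinct combined UMIs (4^5 x 4^5 = 1,048,576)."""
        return 4 ** self.combined_umi_length


_FIVE_PRIME_PATTERNS = ("NNNCGANNNTACNNN", "NNNATCNNNAGTNNN")
_THREE_PRIME_PATTERN = "NNNGTCNNNTAGNNN"


@dataclass(frozen=True)
class SmallRnaLayout:
    """Single-end small RNA-seq layout: 5' UMI block + insert + 3' UMI block + adapter.

    Each 15-nt block interleaves three random trinucleotides with two
    locator trinucleotides.  Two alternative 5' locator sets exist (the
    adapters were pooled to raise early-cycle sequence diversity); one 3'
    set.  ``mismatch_budget`` selects whether the 1-mismatch allowance
    applies per block (default) or is shared across both blocks.
    """

    locator_mismatches: int = 1
    mismatch_budget: str = "per-block"  # or "total"
    umi_block_length: int = 15
    insert_min: int = 18
    insert_max: int = 35
    adapter3: str = "AGATCGGAAGAGCACACGTCT"
    adapter_match_length: int = 10
    adapter_mismatches: int = 0
    five_prime_schemes: tuple[LocatorScheme, ...] = field(default=None)  # type: ignore[assignment]
    three_prime_scheme: LocatorScheme = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.five_prime_schemes is None:
            object.__setattr__(
                self,
                "five_prime_schemes",
                tuple(
                    LocatorScheme(p, self.locator_mismatches, label=f"5p-{i}")
                    for i, p in enumerate(_FIVE_PRIME_PATTERNS)
                ),
            )
        if self.three_prime_scheme is None:
            object.__setattr__(
                self,
                "three_prime_scheme",
                LocatorScheme(_THREE_PRIME_PATTERN, self.locator_mismatches, label="3p"),
            )
        if self.mismatch_budget not in ("per-block", "total"):
            raise ValueError("mismatch_budget must be 'per-block' or 'total'")

    @property
    def combined_umi_length(self) -> int:
        # 9 random bases per block, two blocks
        return len(self.five_prime_schemes[0].umi_positions) + len(
            self.three_prime_scheme.umi_positions
        )

    @property
    def min_trimmed_length(self) -> int:
        # two UMI blocks plus at least one insert base
        return 2 * self.umi_block_length + 1

    @property
    def umi_space_size(self) -> int:
        """Number of distinct combined UMIs (4^18 ~ 6.87e10)."""
        return 4 ** self.combined_umi_length
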