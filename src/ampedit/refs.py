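"""Core domain types shared across the package.

Coordinates are 0-based half-open on the amplicon's forward (reference)
strand throughout the library; user-facing reports convert to 1-based
inclusive. Nick positions are inter-base coordinates: nick ``p`` sits
between reference bases ``p-1`` and ``p``.
"""

from __future__ import annotations

from dataclasses import dataclass

COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

#: IUPAC nucleotide codes -> set of concrete bases matched.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

GUIDE_ROLES = ("pegRNA", "epegRNA", "ngRNA", "dsgRNA", "sgRNA")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC-aware)."""
    return seq.translate(COMPLEMENT)[::-1]


def matches_pattern(seq: str, pattern: str) -> bool:
    """True if ``seq`` matches an IUPAC ``pattern`` of the same length."""
    if len(seq) != len(pattern):
        return False
    return all(b in IUPAC[p] for b, p in zip(seq, pattern.upper()))


@dataclass(frozen=True)
class AmpliconRef:
    """A reference amplicon: the coordinate frame for all quantification."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("amplicon sequence must be non-empty")
        bad = set(self.sequence) - set("ACGT")
        if bad:
            raise ValueError(f"amplicon alphabet must be ACGT, found {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GuideSite:
    """A guide RNA placed on an amplicon.

    ``start`` is the leftmost reference coordinate of the protospacer match
    (the ``len(spacer)`` bases read 5'->3' on ``strand``). The PAM lies
    immediately 3' of the protospacer: at ``start + len(spacer)`` on the +
    strand, at ``start - len(pam)`` on the - strand.

    The nick is placed 3 nt 5' of the PAM on the protospacer strand
    (between protospacer positions 17 and 18 for a 20-nt spacer), the
    canonical SpCas9 nickase geometry.
    """

    role: str
    spacer: str
    strand: str
    start: int
    pam: str = "NGG"
    amplicon_id: str | None = None

    def __post_init__(self) -> None:
        if self.role not in GUIDE_ROLES:
            raise ValueError(f"role must be one of {GUIDE_ROLES}, got {self.role!r}")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if not 14 <= len(self.spacer) <= 21:
            raise ValueError("spacer length must be 14-21 nt")

    @property
    def end(self) -> int:
        """One past the rightmost protospacer coordinate."""
        return self.start + len(self.spacer)

    @property
    def nick_position(self) -> int:
        """Inter-base nick coordinate, 3 nt 5' of the PAM."""
        if self.strand == "+":
            return self.end - 3
        return self.start + 3

    @property
    def pam_interval(self) -> tuple[int, int]:
        """Reference interval of the PAM (half-open)."""
        n = len(self.pam)
        if self.strand == "+":
            return self.end, self.end + n
        return self.start - n, self.start

    def footprint(self) -> tuple[int, int]:
        """Reference interval covered by protospacer + PAM."""
        ps, pe = self.pam_interval
        return min(self.start, ps), max(self.end, pe)

    def protospacer_on_ref(self, ref: AmpliconRef) -> str:
        """Protospacer sequence read 5'->3' on the guide strand."""
        seg = ref.sequence[self.start:self.end]
        return seg if self.strand == "+" else revcomp(seg)

    def validate_against(self, ref: AmpliconRef) -> None:
        """Require the spacer to match the amplicon at its site."""
        if self.start < 0 or self.end > len(ref):
            raise ValueError(f"guide {self.spacer} falls outside amplicon {ref.id}")
        found = self.protospacer_on_ref(ref)
        if found != self.spacer.upper().replace("U", "T"):
            raise ValueError(
                f"spacer {self.spacer} does not match amplicon at "
                f"{self.start} ({self.strand}): found {found}"
            )

    def protospacer_position_to_ref(self, pos1: int) -> int:
        """Map a 1-based protospacer position (1 = PAM-distal) to a
        reference coordinate."""
        if not 1 <= pos1 <= len(self.spacer):
            raise ValueError(f"protospacer position {pos1} outside 1..{len(self.spacer)}")
        if self.strand == "+":
            return self.start + pos1 - 1
        return self.end - pos1


@dataclass(frozen=True)
class QuantWindow:
    """Half-open amplicon interval within which reads are classified."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid window [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def clip(self, length: int) -> "QuantWindow":
        return QuantWindow(max(0, self.start), min(length, self.end))


@dataclass(frozen=True)
class GenotypeBaseline:
    """Ploidy-aware baseline genotype of a cell line.

    A triploid line carrying one wild-type allele starts from a baseline
    of ~33% wild-type genotype; correction is measured against it.
    """

    ploidy: int
    wt_alleles: int

    def __post_init__(self) -> None:
        if self.ploidy < 1:
            raise ValueError("ploidy must be >= 1")
        if not 0 <= self.wt_alleles <= self.ploidy:
            raise ValueError("wt_alleles must lie in [0, ploidy]")

    @property
    def baseline_wt_pct(self) -> float:
        return 100.0 * self.wt_alleles / self.ploidy
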