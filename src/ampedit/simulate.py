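"""Synthetic amplicon-sequencing data: references with planted guide
sites, reads drawn from allele mixtures with a quality and substitution
error model, paired treated/mock off-target read sets, and off-target
nomination tables.

All generators take an integer seed and are deterministic for a fixed
seed and configuration. The read simulator emits full-length single-end
amplicon reads; sequencing errors are i.i.d. per-base substitutions to a
uniformly chosen other base (no indel errors — indels enter only through
allele specifications, isolating indel-classification logic).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .align import Read
from .refs import IUPAC, AmpliconRef, QuantWindow, revcomp

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class AlleleSpec:
    """One allele in a simulated mixture.

    ``edits`` are substitutions (0-based position, ref base, alt base);
    ``indel`` is an optional (position, payload) where a ``str`` payload
    is an insertion at that inter-base coordinate and an ``int`` payload
    a deletion of that many bases starting there. ``weight`` is a
    non-negative count or proportion.
    """

    name: str
    edits: tuple[tuple[int, str, str], ...] = ()
    indel: tuple[int, str | int] | None = None
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError("allele weight must be >= 0")
        positions = [p for p, _, _ in self.edits]
        if sorted(positions) != positions or len(set(positions)) != len(positions):
            raise ValueError("substitution positions must be strictly increasing")

    def apply(self, ref: AmpliconRef) -> str:
        """Build the allele sequence, validating ref bases."""
        seq = list(ref.sequence)
        for pos, refb, altb in self.edits:
            if seq[pos] != refb:
                raise ValueError(
                    f"allele {self.name}: ref base at {pos} is {seq[pos]}, expected {refb}"
                )
            seq[pos] = altb
        out = "".join(seq)
        if self.indel is not None:
            pos, payload = self.indel
            if isinstance(payload, str):
                out = out[:pos] + payload + out[pos:]
            else:
                out = out[:pos] + out[pos + payload:]
        return out


@dataclass(frozen=True)
class ReadSimConfig:
    """Read-set simulation parameters."""

    n_reads: int = 3000
    error_rate: float = 0.0
    base_quality: float = 37.0
    quality_sd: float = 0.0
    seed: int = 0
    exact_counts: bool = True

    def __post_init__(self) -> None:
        if self.n_reads <= 0:
            raise ValueError("n_reads must be > 0")
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must lie in [0, 1]")


def _pattern_instance(pattern: str, rng: np.random.Generator) -> str:
    return "".join(c if len(IUPAC[c]) == 1 else rng.choice(list(IUPAC[c])) for c in pattern.upper())


def make_amplicon(
    length: int,
    seed: int,
    planted_sites: list[tuple[str, str, str, int]] = (),
    id: str = "amplicon",
) -> AmpliconRef:
    """Random amplicon with protospacer+PAM sites planted at fixed positions.

    Each planted site is (spacer, pam_pattern, strand, position) with
    ``position`` the leftmost reference coordinate of the protospacer.
    Overlapping plants demanding different bases at a shared position
    raise a ``ValueError`` naming the positions.
    """
    rng = np.random.default_rng(seed)
    fixed: dict[int, str] = {}
    conflicts: list[int] = []

    def assign(pos: int, base: str) -> None:
        if pos < 0 or pos >= length:
            raise ValueError(f"planted site extends outside amplicon at position {pos}")
        if pos in fixed and fixed[pos] != base:
            conflicts.append(pos)
        else:
            fixed[pos] = base

    for spacer, pam_pattern, strand, position in planted_sites:
        spacer = spacer.upper().replace("U", "T")
        proto = spacer if strand == "+" else revcomp(spacer)
        for i, b in enumerate(proto):
            assign(position + i, b)
        pam = _pattern_instance(pam_pattern, rng)
        if strand == "+":
            pam_start = position + len(spacer)
            pam_fwd = pam
        else:
            pam_start = position - len(pam)
            pam_fwd = revcomp(pam)
        for i, b in enumerate(pam_fwd):
            # degenerate positions yield to an existing compatible base
            pat_c = pam_pattern.upper()[i if strand == "+" else len(pam) - 1 - i]
            ref_pos = pam_start + i
            if ref_pos in fixed and len(IUPAC[pat_c]) > 1:
                want = IUPAC[pat_c] if strand == "+" else revcomp(IUPAC[pat_c])[::-1]
                if fixed[ref_pos] in want:
                    continue
            assign(ref_pos, b)
    if conflicts:
        raise ValueError(
            f"planted sites demand conflicting bases at positions {sorted(set(conflicts))}"
        )
    seq = rng.choice(_BASES, size=length)
    for pos, b in fixed.items():
        seq[pos] = b
    return AmpliconRef(id=id, sequence="".join(seq))


def _allele_counts(
    alleles: list[AlleleSpec], cfg: ReadSimConfig, rng: np.random.Generator
) -> np.ndarray:
    weights = np.array([a.weight for a in alleles], dtype=float)
    if weights.sum() <= 0:
        raise ValueError("allele weights are all zero")
    if not cfg.exact_counts:
        return rng.multinomial(cfg.n_reads, weights / weights.sum())
    # largest-remainder apportionment so counts sum exactly to n_reads
    quota = cfg.n_reads * weights / weights.sum()
    counts = np.floor(quota).astype(int)
    remainder = cfg.n_reads - counts.sum()
    order = np.argsort(-(quota - counts))
    counts[order[:remainder]] += 1
    return counts


def simulate_reads(
    ref: AmpliconRef, alleles: list[AlleleSpec], cfg: ReadSimConfig
) -> list[Read]:
    """Simulate full-amplicon reads from an allele mixture.

    With ``exact_counts`` and ``error_rate == 0`` the multiset of read
    sequences equals the allele sequences at their apportioned counts.
    """
    rng = np.random.default_rng(cfg.seed)
    counts = _allele_counts(alleles, cfg, rng)
    reads: list[Read] = []
    idx = 0
    for allele, n in zip(alleles, counts):
        base_seq = allele.apply(ref)
        arr0 = np.frombuffer(base_seq.encode(), dtype="S1")
        for _ in range(n):
            arr = arr0
            if cfg.error_rate > 0:
                errs = np.nonzero(rng.random(arr0.size) < cfg.error_rate)[0]
                if errs.size:
                    arr = arr0.copy()
                    for p in errs:
                        cur = arr[p].decode()
                        arr[p] = rng.choice([b for b in "ACGT" if b != cur]).encode()
            if cfg.quality_sd > 0:
                q = int(round(rng.normal(cfg.base_quality, cfg.quality_sd)))
            else:
                q = int(round(cfg.base_quality))
            q = min(41, max(2, q))
            reads.append(
                Read(
                    name=f"{ref.id}:{allele.name}:{idx}",
                    sequence=arr.tobytes().decode(),
                    qualities=(q,) * arr.size,
                )
            )
            idx += 1
    return reads


@dataclass(frozen=True)
class OffTargetScenario:
    """True editing levels for one off-target site, both arms.

    Percentages are of all reads; the mock arm models background
    (sequencing/PCR artifacts present without editor treatment).
    """

    site_id: str
    treated_indel_pct: float = 0.0
    treated_sub_pct: float = 0.0
    mock_indel_pct: float = 0.0
    mock_sub_pct: float = 0.0
    reads_per_arm: int = 2000
    seed: int = 0
    error_rate: float = 0.0

    def __post_init__(self) -> None:
        for v in (
            self.treated_indel_pct,
            self.treated_sub_pct,
            self.mock_indel_pct,
            self.mock_sub_pct,
        ):
            if not 0.0 <= v <= 100.0:
                raise ValueError("scenario percentages must lie in [0, 100]")


def _arm_alleles(
    ref: AmpliconRef, window: QuantWindow, indel_pct: float, sub_pct: float
) -> list[AlleleSpec]:
    mid = (window.start + window.end) // 2
    sub_pos = window.start + (window.end - window.start) // 3
    refb = ref.sequence[sub_pos]
    altb = "ACGT"[("ACGT".index(refb) + 1) % 4]
    alleles = [AlleleSpec("wt", weight=max(0.0, 100.0 - indel_pct - sub_pct))]
    if indel_pct > 0:
        alleles.append(AlleleSpec("indel", indel=(mid, 3), weight=indel_pct))
    if sub_pct > 0:
        alleles.append(
            AlleleSpec("sub", edits=((sub_pos, refb, altb),), weight=sub_pct)
        )
    return alleles


def simulate_offtarget_pair(
    ref: AmpliconRef,
    scenario: OffTargetScenario,
    window: QuantWindow | None = None,
) -> tuple[list[Read], list[Read]]:
    """Paired treated/mock read sets whose true indel and substitution
    fractions inside ``window`` equal the scenario values (exactly up to
    count apportionment). ``window`` defaults to the central half of the
    amplicon."""
    if window is None:
        n = len(ref)
        window = QuantWindow(n // 4, n - n // 4)
    treated = simulate_reads(
        ref,
        _arm_alleles(ref, window, scenario.treated_indel_pct, scenario.treated_sub_pct),
        ReadSimConfig(
            n_reads=scenario.reads_per_arm,
            error_rate=scenario.error_rate,
            seed=scenario.seed,
        ),
    )
    mock = simulate_reads(
        ref,
        _arm_alleles(ref, window, scenario.mock_indel_pct, scenario.mock_sub_pct),
        ReadSimConfig(
            n_reads=scenario.reads_per_arm,
            error_rate=scenario.error_rate,
            seed=scenario.seed + 1,
        ),
    )
    return treated, mock


def make_nomination_table(
    n_sites_per_guide: int,
    guides: list[str],
    seed: int,
    contig_id: str = "chr1",
    site_spacing: int = 150,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Synthetic off-target nomination table plus the genome it maps to.

    Emulates an in vitro nomination assay's output: per guide,
    ``n_sites_per_guide`` sites on a synthetic contig, each with a 23-nt
    protospacer+PAM sequence and a nomination read count strictly
    decreasing within the guide. Returns (table, {contig_id: sequence}).
    """
    if n_sites_per_guide < 1:
        raise ValueError("n_sites_per_guide must be >= 1")
    rng = np.random.default_rng(seed)
    total = n_sites_per_guide * len(guides)
    contig = "".join(rng.choice(_BASES, size=100 + total * site_spacing + 100))
    rows = []
    k = 0
    for guide in guides:
        # strictly ranked counts within guide
        counts = np.sort(rng.choice(np.arange(10, 100_000), size=n_sites_per_guide, replace=False))[::-1]
        for j in range(n_sites_per_guide):
            start = 100 + k * site_spacing
            strand = "+" if rng.random() < 0.5 else "-"
            seg = contig[start:start + 23]
            seq = seg if strand == "+" else revcomp(seg)
            rows.append(
                {
                    "site_id": f"{guide}_OT{j + 1}",
                    "guide_id": guide,
                    "chrom": contig_id,
                    "start": start,
                    "strand": strand,
                    "sequence": seq,
                    "nomination_reads": int(counts[j]),
                }
            )
            k += 1
    return pd.DataFrame(rows), {contig_id: contig}
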