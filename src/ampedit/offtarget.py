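"""Off-target panel construction and treated-vs-mock quantification.

From a nomination table (e.g. an in vitro cleavage assay's ranked
sites), the top 32 sites per guide are selected; each site's amplicon is
the 23-nt protospacer+PAM padded by 25 nt on either side (73 nt for an
interior site), and its quantification window runs from 10 bp upstream
of the protospacer to 10 bp downstream of the PAM (43 bp for a 20+3
site). Indels and substitutions are quantified in both arms and compared
as log2 fold-change treated/mock; sites at or above 0.5 log2 units
(a 1.4-fold increase) are flagged. A pseudocount of 0.01 percentage
points guards against zero-mock division.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import pandas as pd

from .align import Read
from .be_alleles import abe_window_transition_pct
from .quant import QuantResult, quantify
from .refs import AmpliconRef, GuideSite, QuantWindow

TOP_K_PER_GUIDE = 32
PAD = 25
WINDOW_FLANK = 10
LOG2FC_THRESHOLD = 0.5
EPSILON = 0.01  # percentage-point pseudocount in log2 fold-changes

CONTEXT_PRECEDENCE = ("exonic", "UTR", "promoter", "lncRNA", "intronic")


@dataclass(frozen=True)
class OffTargetSite:
    """A nominated locus: 23-nt protospacer+PAM with its genomic placement."""

    site_id: str
    guide_id: str
    chrom: str
    start: int
    strand: str
    sequence: str
    nomination_reads: int

    def __post_init__(self) -> None:
        if len(self.sequence) != 23:
            raise ValueError("off-target site sequence must be 23 nt (protospacer+PAM)")
        if self.nomination_reads < 0:
            raise ValueError("nomination read count must be >= 0")


def sites_from_table(table: pd.DataFrame) -> list[OffTargetSite]:
    return [
        OffTargetSite(
            site_id=row.site_id, guide_id=row.guide_id, chrom=row.chrom,
            start=int(row.start), strand=row.strand, sequence=row.sequence,
            nomination_reads=int(row.nomination_reads),
        )
        for row in table.itertuples()
    ]


def select_top_sites(
    nominations: pd.DataFrame, k_per_guide: int = TOP_K_PER_GUIDE
) -> pd.DataFrame:
    """Top ``k_per_guide`` sites per guide by nomination read count, ties
    broken by ascending genomic coordinate."""
    if nominations["site_id"].duplicated().any():
        dups = nominations.loc[nominations["site_id"].duplicated(), "site_id"].tolist()
        raise ValueError(f"duplicate site ids in nomination table: {dups}")
    return (
        nominations.sort_values(
            ["guide_id", "nomination_reads", "chrom", "start"],
            ascending=[True, False, True, True],
        )
        .groupby("guide_id", sort=True)
        .head(k_per_guide)
        .reset_index(drop=True)
    )


def build_padded_amplicon(
    site: OffTargetSite, reference: dict[str, str] | str, pad: int = PAD
) -> tuple[AmpliconRef, int]:
    """Amplicon = protospacer+PAM padded by ``pad`` nt on either side.

    Returns the amplicon and the offset of the site within it (``pad``
    unless clipped at a contig end, which warns). Raises if the site
    falls off its contig.
    """
    contig = reference[site.chrom] if isinstance(reference, dict) else reference
    t0, t1 = site.start, site.start + 23
    if t0 < 0 or t1 > len(contig):
        raise ValueError(f"site {site.site_id} falls outside contig {site.chrom}")
    a0 = t0 - pad
    a1 = t1 + pad
    if a0 < 0 or a1 > len(contig):
        warnings.warn(
            f"padded amplicon for {site.site_id} clipped at contig end", stacklevel=2
        )
        a0 = max(0, a0)
        a1 = min(len(contig), a1)
    return AmpliconRef(id=site.site_id, sequence=contig[a0:a1]), t0 - a0


def build_site_quant_window(
    site: OffTargetSite,
    amplicon: AmpliconRef,
    offset: int = PAD,
    flank: int = WINDOW_FLANK,
) -> QuantWindow:
    """Window from ``flank`` bp upstream of the protospacer through
    ``flank`` bp downstream of the PAM — one physical interval whichever
    strand the site is on — clipped to the amplicon."""
    return QuantWindow(max(0, offset - flank), offset + 23 + flank).clip(len(amplicon))


def site_guide(site: OffTargetSite, amplicon: AmpliconRef, offset: int = PAD) -> GuideSite:
    """Place the site's protospacer on its padded amplicon as a guide."""
    if site.strand == "+":
        start, pam = offset, site.sequence[20:]
    else:
        start, pam = offset + 3, site.sequence[20:]
    return GuideSite(
        role="sgRNA", spacer=site.sequence[:20], strand=site.strand,
        start=start, pam=pam, amplicon_id=amplicon.id,
    )


def log2_fold_change(
    treated_pct: float, mock_pct: float, epsilon: float = EPSILON
) -> float:
    return math.log2((treated_pct + epsilon) / (mock_pct + epsilon))


@dataclass(frozen=True)
class SiteQuant:
    """Treated/mock metrics and their comparison for one panel site."""

    site_id: str
    treated_indel_pct: float | None
    treated_sub_pct: float | None
    mock_indel_pct: float | None
    mock_sub_pct: float | None
    log2fc_indel: float | None
    log2fc_sub: float | None
    bg_subtracted_indel_pct: float | None
    bg_subtracted_sub_pct: float | None
    flagged: bool
    amplifiable: bool = True
    context: str | None = None

    @property
    def max_log2fc(self) -> float | None:
        vals = [v for v in (self.log2fc_indel, self.log2fc_sub) if v is not None]
        return max(vals) if vals else None


def quantify_site(
    treated: list[Read],
    mock: list[Read],
    site: OffTargetSite,
    amplicon: AmpliconRef,
    mode: str = "PE",
    offset: int = PAD,
    threshold_log2: float = LOG2FC_THRESHOLD,
    min_mean_q: float = 30.0,
) -> SiteQuant:
    """Quantify both arms at one site and compare them.

    PE mode measures window substitutions; ABE mode measures A->G
    transitions at protospacer positions 4-10. An arm with no aligned
    reads marks the site not amplifiable and excludes it from flagging.
    """
    if mode not in ("PE", "ABE"):
        raise ValueError("mode must be 'PE' or 'ABE'")
    window = build_site_quant_window(site, amplicon, offset)
    qt = quantify(amplicon, treated, window, min_mean_q)
    qm = quantify(amplicon, mock, window, min_mean_q)
    if qt.aligned_total == 0 or qm.aligned_total == 0:
        return SiteQuant(
            site_id=site.site_id, treated_indel_pct=None, treated_sub_pct=None,
            mock_indel_pct=None, mock_sub_pct=None, log2fc_indel=None,
            log2fc_sub=None, bg_subtracted_indel_pct=None,
            bg_subtracted_sub_pct=None, flagged=False, amplifiable=False,
        )
    if mode == "ABE":
        guide = site_guide(site, amplicon, offset)
        ts = abe_window_transition_pct(qt, guide)
        ms = abe_window_transition_pct(qm, guide)
    else:
        ts = qt.substitution_pct()
        ms = qm.substitution_pct()
    ti, mi = qt.indel_pct, qm.indel_pct
    l2i = log2_fold_change(ti, mi)
    l2s = log2_fold_change(ts, ms)
    return SiteQuant(
        site_id=site.site_id,
        treated_indel_pct=ti, treated_sub_pct=ts,
        mock_indel_pct=mi, mock_sub_pct=ms,
        log2fc_indel=l2i, log2fc_sub=l2s,
        bg_subtracted_indel_pct=max(0.0, ti - mi),
        bg_subtracted_sub_pct=max(0.0, ts - ms),
        flagged=max(l2i, l2s) >= threshold_log2,
    )


def flag_sites(
    quants: list[SiteQuant], threshold_log2: float = LOG2FC_THRESHOLD
) -> list[SiteQuant]:
    """Amplifiable sites whose indel or substitution log2 fold-change
    meets the threshold (inclusive)."""
    return [
        q
        for q in quants
        if q.amplifiable and q.max_log2fc is not None and q.max_log2fc >= threshold_log2
    ]


def annotate_context(
    site: OffTargetSite, features: pd.DataFrame | list[tuple[str, int, int, str]]
) -> str:
    """Genomic-context label by feature overlap.

    ``features`` is BED-like: (chrom, start, end, label) with labels from
    {exonic, UTR, promoter, lncRNA, intronic}. Precedence when a site
    overlaps several features: exonic > UTR > promoter > lncRNA >
    intronic; no overlap is intergenic.
    """
    if isinstance(features, pd.DataFrame):
        rows = list(features.itertuples(index=False))
    else:
        rows = features
    s0, s1 = site.start, site.start + 23
    hits: set[str] = set()
    for i, row in enumerate(rows):
        try:
            chrom, start, end, label = row[0], int(row[1]), int(row[2]), row[3]
        except (ValueError, TypeError, IndexError) as exc:
            raise ValueError(f"malformed feature interval at line {i + 1}: {row!r}") from exc
        if start > end:
            raise ValueError(f"malformed feature interval at line {i + 1}: start > end")
        if chrom == site.chrom and start < s1 and end > s0:
            hits.add(label)
    unknown = hits - set(CONTEXT_PRECEDENCE)
    if unknown:
        raise ValueError(f"unknown feature labels: {sorted(unknown)}")
    for label in CONTEXT_PRECEDENCE:
        if label in hits:
            return label
    return "intergenic"
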