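"""Quantification-window construction and editing-outcome metrics.

The pipeline mirrors standard amplicon-editing quantification with
indel-discarding semantics: reads passing a mean-quality filter are
globally aligned; any read with an insertion or deletion overlapping the
quantification window is discarded (it counts toward the indel rate);
per-position nucleotide percentages, genotype percentages, and
substitution rates are computed over the retained reads but normalized
to all aligned reads, so that

    indel% = 100 * discarded / aligned_total
    genotype%(pos, base) = 100 * retained reads with `base` at `pos` / aligned_total

and pathogenic-allele correction rescales the wild-type genotype against
the cell line's ploidy baseline:

    correction% = 100 * max(0, genotype% - baseline%) / (100 - baseline%)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .align import Read, ReadAlignment, align_read, quality_filter
from .refs import AmpliconRef, GenotypeBaseline, GuideSite, QuantWindow

NICK_FLANK = 10  # bp added on each side of the outermost nicks
BASES = ("A", "C", "G", "T")


def build_pe_quant_window(
    guides: list[GuideSite],
    flap_end: int | None = None,
    amplicon_length: int | None = None,
) -> QuantWindow:
    """Prime-editing quantification window.

    Spans 10 bp upstream of the most 5' nick through 10 bp downstream of
    the most 3' nick over all supplied guides (pegRNA/epegRNA/ngRNA/
    dsgRNA). If the reverse-transcribed 3' flap extends past a bound,
    ``flap_end`` +/- 10 replaces that bound.
    """
    if not guides:
        raise ValueError("at least one guide with a nick position is required")
    amp_ids = {g.amplicon_id for g in guides if g.amplicon_id is not None}
    if len(amp_ids) > 1:
        raise ValueError(f"guides span multiple amplicons: {sorted(amp_ids)}")
    nicks = [g.nick_position for g in guides]
    start = min(nicks) - NICK_FLANK
    end = max(nicks) + NICK_FLANK
    if flap_end is not None:
        if flap_end + NICK_FLANK > end:
            end = flap_end + NICK_FLANK
        elif flap_end - NICK_FLANK < start:
            start = flap_end - NICK_FLANK
    win = QuantWindow(max(0, start), end)
    if amplicon_length is not None:
        win = win.clip(amplicon_length)
    return win


def build_be_quant_window(
    sgRNA: GuideSite, amplicon_length: int | None = None
) -> QuantWindow:
    """Base-editing quantification window.

    A 20-bp window centered 10 bp upstream of the SpCas9 cut site — which
    coincides exactly with the 20-nt protospacer interval.
    """
    if len(sgRNA.spacer) != 20:
        raise ValueError("base-editing window requires a 20-nt protospacer")
    win = QuantWindow(sgRNA.start, sgRNA.end)
    if amplicon_length is not None and (win.start < 0 or win.end > amplicon_length):
        warnings.warn("base-editing window clipped to amplicon", stacklevel=2)
        win = win.clip(amplicon_length)
    return win


def classify_indel_read(alignment: ReadAlignment, window: QuantWindow) -> str:
    """'discarded' if any insertion or deletion overlaps the window
    (insertions at a boundary overlap), else 'retained'."""
    return "discarded" if alignment.has_indel_overlapping(window.start, window.end) else "retained"


@dataclass(frozen=True)
class QuantResult:
    """Per-sample quantification output for one amplicon."""

    ref: AmpliconRef
    window: QuantWindow
    total_reads: int
    q_filtered_reads: int
    aligned_total: int
    retained: int
    discarded: int
    nuc_pct: pd.DataFrame  # index: window positions, columns ACGT
    retained_alignments: tuple[ReadAlignment, ...]

    def __post_init__(self) -> None:
        assert self.retained + self.discarded == self.aligned_total
        unaligned = self.q_filtered_reads - self.aligned_total
        assert unaligned >= 0

    @property
    def indel_pct(self) -> float | None:
        """100 x discarded / aligned_total; None when nothing aligned."""
        if self.aligned_total == 0:
            return None
        return 100.0 * self.discarded / self.aligned_total

    def genotype_pct(self, position: int, base: str) -> float:
        """Percent of all aligned reads that are retained and carry
        ``base`` at ``position`` (a window coordinate)."""
        if not self.window.contains(position):
            raise ValueError(
                f"position {position} outside window "
                f"[{self.window.start}, {self.window.end})"
            )
        return float(self.nuc_pct.at[position, base.upper()])

    def substitution_pct(self, window: QuantWindow | None = None) -> float | None:
        """Percent of aligned reads retained with >=1 substitution in the window."""
        if self.aligned_total == 0:
            return None
        win = window or self.window
        n = sum(
            1
            for a in self.retained_alignments
            if any(win.contains(p) for p in a.substitutions)
        )
        return 100.0 * n / self.aligned_total


def quantify(
    ref: AmpliconRef,
    reads: list[Read],
    window: QuantWindow,
    min_mean_q: float = 30.0,
) -> QuantResult:
    """Run the full per-sample quantification: quality filter, align,
    indel-classify against ``window``, and tabulate nucleotide percentages."""
    kept = quality_filter(reads, min_mean_q)
    retained_alns: list[ReadAlignment] = []
    aligned_total = 0
    discarded = 0
    for r in kept:
        aln = align_read(r, ref)
        if not aln.aligned:
            continue
        aligned_total += 1
        if classify_indel_read(aln, window) == "discarded":
            discarded += 1
        else:
            retained_alns.append(aln)

    positions = np.arange(window.start, window.end)
    counts = np.zeros((len(positions), 4), dtype=np.int64)
    if retained_alns:
        mat = np.frombuffer(
            "".join(a.calls[window.start:window.end] for a in retained_alns).encode(),
            dtype="S1",
        ).reshape(len(retained_alns), len(positions))
        for j, b in enumerate(BASES):
            counts[:, j] = (mat == b.encode()).sum(axis=0)
    denom = max(aligned_total, 1)
    nuc_pct = pd.DataFrame(
        100.0 * counts / denom, index=positions, columns=list(BASES)
    )
    return QuantResult(
        ref=ref,
        window=window,
        total_reads=len(reads),
        q_filtered_reads=len(kept),
        aligned_total=aligned_total,
        retained=len(retained_alns),
        discarded=discarded,
        nuc_pct=nuc_pct,
        retained_alignments=tuple(retained_alns),
    )


def indel_pct(result: QuantResult) -> float | None:
    return result.indel_pct


def genotype_pct(result: QuantResult, position: int, base: str) -> float:
    return result.genotype_pct(position, base)


def substitution_pct(result: QuantResult, window: QuantWindow | None = None) -> float | None:
    return result.substitution_pct(window)


def pathogenic_allele_correction(
    result: QuantResult,
    baseline: GenotypeBaseline,
    wt_position: int,
    wt_base: str,
) -> float:
    """Fraction of pathogenic alleles converted to wild type, given the
    line's baseline wild-type allele fraction."""
    b = baseline.baseline_wt_pct
    if b >= 100.0:
        raise ValueError("baseline is fully wild type: no pathogenic alleles to correct")
    g = result.genotype_pct(wt_position, wt_base)
    return 100.0 * max(0.0, g - b) / (100.0 - b)
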