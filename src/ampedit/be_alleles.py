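"""Base-editing product-allele enumeration and read classification.

Protospacer positions are 1-based with position 1 PAM-distal and the
SpCas9 PAM spanning positions 21-23. The substrate base is A for adenine
base editors (A->G product) and C for cytosine base editors (C->T).

A read (already indel-filtered) is classified by the subset of substrate
positions it carries in converted form:

* ``precise_wt`` — subset equals exactly the targeted positions and the
  protospacer carries no other change;
* ``bystander`` — subset contains at least one non-target conversion
  (with or without the target);
* ``unedited`` — empty subset;
* ``other``   — a protospacer substitution that is not a substrate
  conversion (neither category);
* ``partial_target`` — a non-empty proper subset of a multi-position
  target with no bystander (only arises when several positions are
  targeted jointly).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterator

from .quant import QuantResult
from .refs import GuideSite, revcomp

SUBSTRATE = {"ABE": ("A", "G"), "CBE": ("C", "T")}
ABE_WINDOW = (4, 10)  # inclusive protospacer positions for the ABE activity window


@dataclass(frozen=True)
class BEAlleleTable:
    """Editable/target positions of a protospacer plus classified allele rows."""

    protospacer: str
    editor_class: str
    editable_positions: tuple[int, ...]
    target_positions: frozenset[int]
    rows: tuple[tuple[frozenset[int], int, float], ...] = ()  # (subset, count, pct)

    def __post_init__(self) -> None:
        if not self.target_positions <= set(self.editable_positions):
            raise ValueError("target positions must be a subset of editable positions")


def substrate_positions(protospacer: str, editor_class: str) -> tuple[int, ...]:
    """1-based protospacer positions holding the substrate base."""
    sub, _ = SUBSTRATE[editor_class]
    return tuple(i + 1 for i, b in enumerate(protospacer.upper()) if b == sub)


def enumerate_product_alleles(
    protospacer: str, editor_class: str
) -> Iterator[frozenset[int]]:
    """Every theoretical deamination product allele: all non-empty subsets
    of substrate-base positions (2^k - 1 patterns for k substrate bases).

    The enumeration is lazy; classification never materializes it, so
    substrate-rich protospacers stay tractable.
    """
    if not 19 <= len(protospacer) <= 20:
        raise ValueError("protospacer must be 19-20 nt")
    positions = substrate_positions(protospacer, editor_class)
    if not positions:
        warnings.warn(
            f"no {SUBSTRATE[editor_class][0]} in protospacer: no product alleles",
            stacklevel=2,
        )
        return
    for r in range(1, len(positions) + 1):
        for combo in combinations(positions, r):
            yield frozenset(combo)


@dataclass(frozen=True)
class BEClassification:
    """Read-category percentages, all normalized to aligned_total."""

    precise_wt_pct: float
    bystander_pct: float
    unedited_pct: float
    other_pct: float
    partial_target_pct: float
    bystander_with_target_pct: float  # bystander alleles that also carry the target
    bystander_only_pct: float  # bystander alleles without the target
    counts: dict[str, int]
    allele_rows: tuple[tuple[frozenset[int], int, float], ...]


def _read_protospacer(calls: str, site: GuideSite) -> str:
    seg = calls[site.start:site.end]
    return seg if site.strand == "+" else revcomp(seg)


def classify_be_reads(
    result: QuantResult, site: GuideSite, target_positions: frozenset[int] | set[int]
) -> BEClassification:
    """Classify retained reads by their conversion subset.

    ``result`` must come from quantification against the base-editing
    window of ``site``; the editor class is inferred from the reference
    base at the targeted positions.
    """
    proto_ref = site.protospacer_on_ref(result.ref)
    target = frozenset(target_positions)
    ref_bases = {proto_ref[p - 1] for p in target}
    if len(ref_bases) != 1 or next(iter(ref_bases)) not in ("A", "C"):
        raise ValueError("target positions must all hold one substrate base (A or C)")
    sub = next(iter(ref_bases))
    editor = "ABE" if sub == "A" else "CBE"
    prod = SUBSTRATE[editor][1]
    editable = substrate_positions(proto_ref, editor)

    counts = {"precise_wt": 0, "bystander": 0, "unedited": 0, "other": 0,
              "partial_target": 0, "bystander_with_target": 0, "bystander_only": 0}
    allele_counts: dict[frozenset[int], int] = {}
    for aln in result.retained_alignments:
        proto = _read_protospacer(aln.calls, site)
        subset = set()
        other = False
        for i, (rb, qb) in enumerate(zip(proto_ref, proto)):
            if qb == rb:
                continue
            if rb == sub and qb == prod:
                subset.add(i + 1)
            else:
                other = True
                break
        if other:
            counts["other"] += 1
            continue
        fs = frozenset(subset)
        allele_counts[fs] = allele_counts.get(fs, 0) + 1
        if not subset:
            counts["unedited"] += 1
        elif fs == target:
            counts["precise_wt"] += 1
        elif subset - target:
            counts["bystander"] += 1
            if target <= subset:
                counts["bystander_with_target"] += 1
            else:
                counts["bystander_only"] += 1
        else:
            counts["partial_target"] += 1

    denom = max(result.aligned_total, 1)
    pct = lambda k: 100.0 * counts[k] / denom
    rows = tuple(
        (fs, n, 100.0 * n / denom)
        for fs, n in sorted(allele_counts.items(), key=lambda kv: (-kv[1], sorted(kv[0])))
    )
    return BEClassification(
        precise_wt_pct=pct("precise_wt"),
        bystander_pct=pct("bystander"),
        unedited_pct=pct("unedited"),
        other_pct=pct("other"),
        partial_target_pct=pct("partial_target"),
        bystander_with_target_pct=pct("bystander_with_target"),
        bystander_only_pct=pct("bystander_only"),
        counts=counts,
        allele_rows=rows,
    )


def allele_pattern(subset: frozenset[int], editor_class: str = "ABE") -> str:
    """Human-readable conversion pattern, e.g. ``"A5G+A7G"``."""
    sub, prod = SUBSTRATE[editor_class]
    if not subset:
        return "WT"
    return "+".join(f"{sub}{p}{prod}" for p in sorted(subset))


def abe_window_transition_pct(
    result: QuantResult,
    site: GuideSite,
    window_positions: tuple[int, int] = ABE_WINDOW,
) -> float:
    """Percent of all aligned reads retained with >=1 A->G conversion
    (protospacer-strand orientation) at protospacer positions 4-10."""
    proto_ref = site.protospacer_on_ref(result.ref)
    lo, hi = window_positions
    a_positions = [
        p for p in range(lo, min(hi, len(proto_ref)) + 1) if proto_ref[p - 1] == "A"
    ]
    if not a_positions:
        warnings.warn("no adenine in the ABE activity window", stacklevel=2)
        return 0.0
    n = 0
    for aln in result.retained_alignments:
        proto = _read_protospacer(aln.calls, site)
        if any(proto[p - 1] == "G" for p in a_positions):
            n += 1
    return 100.0 * n / max(result.aligned_total, 1)
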