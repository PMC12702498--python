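"""Enumeration and annotation of prime-editing guide designs.

Covers protospacer discovery on both strands for a set of PAM patterns,
the 5' spacer rule for U6-driven transcription (19/20/21-nt variants),
PBS x RTT design grids, synonymous (silent) edit sets that disrupt the
pegRNA PAM or protospacer seed, PE3 vs PE3b nick classification, and
dead-sgRNA (dsgRNA) placement.

Signed distances between guides are measured nick-to-nick in the
pegRNA's PAM-strand orientation: negative values lie 5' of the pegRNA
nick on its PAM strand. This reproduces labels such as "+49 ngRNA" and
"non-PAM -44 dsgRNA".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

from Bio.Seq import Seq

from .refs import AmpliconRef, GuideSite, IUPAC, matches_pattern, revcomp

SEED_POSITIONS = (13, 20)  # PAM-proximal protospacer seed, 1-based inclusive
DSG_DISTANCE_WINDOWS = ((-60, -30), (30, 60))
DSG_SPACER_LENGTHS = (14, 15)


@dataclass(frozen=True)
class EditSpec:
    """A single-base edit on the amplicon."""

    position: int
    ref: str
    alt: str
    label: str = "corrective"  # pathogenic | corrective | silent

    def __post_init__(self) -> None:
        if self.label not in ("pathogenic", "corrective", "silent"):
            raise ValueError(f"unknown edit label {self.label!r}")

    def check_against(self, seq: str) -> None:
        if seq[self.position] != self.ref:
            raise ValueError(
                f"edit at {self.position}: sequence has {seq[self.position]}, "
                f"expected {self.ref}"
            )


@dataclass(frozen=True)
class ProtospacerHit:
    site: GuideSite
    pam_pattern: str
    distance_to_edit: int | None = None


def find_protospacers(
    seq: str | AmpliconRef,
    pam_patterns: list[str] = ("NGG",),
    proto_len: int = 20,
    role: str = "pegRNA",
    edit_position: int | None = None,
) -> list[ProtospacerHit]:
    """Every ``proto_len``-nt protospacer adjacent to a matching PAM, both strands.

    ``distance_to_edit`` (when an edit position is given) is the signed
    nick-to-edit offset in the protospacer's PAM-strand orientation.
    """
    s = seq.sequence if isinstance(seq, AmpliconRef) else seq.upper()
    amp_id = seq.id if isinstance(seq, AmpliconRef) else None
    hits: list[ProtospacerHit] = []
    for pat in pam_patterns:
        plen = len(pat)
        for i in range(len(s) - proto_len + 1):
            # + strand: PAM immediately 3' of protospacer
            if i + proto_len + plen <= len(s) and matches_pattern(
                s[i + proto_len:i + proto_len + plen], pat
            ):
                site = GuideSite(
                    role=role, spacer=s[i:i + proto_len], strand="+", start=i,
                    pam=s[i + proto_len:i + proto_len + plen], amplicon_id=amp_id,
                )
                d = None if edit_position is None else edit_position - site.nick_position
                hits.append(ProtospacerHit(site, pat, d))
            # - strand: PAM 5' of the interval on the reference
            if i - plen >= 0 and matches_pattern(revcomp(s[i - plen:i]), pat):
                site = GuideSite(
                    role=role, spacer=revcomp(s[i:i + proto_len]), strand="-", start=i,
                    pam=revcomp(s[i - plen:i]), amplicon_id=amp_id,
                )
                d = None if edit_position is None else site.nick_position - edit_position
                hits.append(ProtospacerHit(site, pat, d))
    hits.sort(key=lambda h: (h.site.start, h.site.strand, h.pam_pattern))
    return hits


@dataclass(frozen=True)
class SpacerVariant:
    """A spacer after applying the 5' G rule for U6 transcription."""

    sequence: str
    tag: str
    disfavored: bool = False

    def __len__(self) -> int:
        return len(self.sequence)


def spacer_5prime_rule(protospacer_20nt: str) -> SpacerVariant:
    """Choose the spacer variant for a 20-nt protospacer.

    U6-driven transcription wants a leading purine. If the protospacer
    already starts with G, use it as-is (20 nt). If position 2 is G,
    truncate to a 19-nt spacer with a genome-matched 5' G — these
    outperform 21-nt 5'-G-extended spacers almost uniformly. Otherwise
    append a mismatched 5' G (21 nt), tagged disfavored since 5' G
    extensions can diminish nuclease activity and editing efficiency.
    """
    p = protospacer_20nt.upper()
    if len(p) != 20:
        raise ValueError("protospacer must be 20 nt")
    if p[0] == "G":
        return SpacerVariant(p, "20-nt")
    if p[1] == "G":
        return SpacerVariant(p[1:], "19-nt genome-matched 5'G")
    return SpacerVariant("G" + p, "21-nt appended 5'G", disfavored=True)


@dataclass(frozen=True)
class PegDesign:
    """One pegRNA/epegRNA design grid point."""

    site: GuideSite
    spacer_variant: SpacerVariant
    pbs_len: int
    rtt_len: int
    edits: tuple[EditSpec, ...]
    silent_edits: tuple[EditSpec, ...]
    name: str

    @property
    def nick_position(self) -> int:
        return self.site.nick_position

    @property
    def flap_end(self) -> int:
        """Inter-base coordinate of the 3' flap terminus (nick +/- RTT
        length in the edited-strand direction)."""
        if self.site.strand == "+":
            return self.nick_position + self.rtt_len
        return self.nick_position - self.rtt_len


def _rtt_covers(site: GuideSite, rtt_len: int, position: int) -> bool:
    nick = site.nick_position
    if site.strand == "+":
        return nick <= position < nick + rtt_len
    return nick - rtt_len <= position < nick


def enumerate_peg_designs(
    site: GuideSite,
    edits: list[EditSpec],
    pbs_range: range,
    rtt_range: range,
    silent_edits: tuple[EditSpec, ...] = (),
    pam_tag: str = "NGG1",
) -> list[PegDesign]:
    """Cartesian PBS x RTT grid, keeping designs whose RTT covers every
    intended edit (corrective plus silent). Edits on the wrong side of
    the nick cannot be reached by any RTT and empty the grid with a
    warning."""
    all_edits = tuple(edits) + tuple(silent_edits)
    nick = site.nick_position
    max_rtt = max(rtt_range)
    unreachable = [
        e for e in all_edits if not _rtt_covers(site, max_rtt, e.position)
    ]
    for e in unreachable:
        side = "5'" if (site.strand == "+") == (e.position < nick) else "beyond max RTT reach from"
        warnings.warn(
            f"edit at {e.position} excluded: lies {side} the nick at {nick}",
            stacklevel=2,
        )
    if unreachable:
        return []
    variant = spacer_5prime_rule(site.spacer) if len(site.spacer) == 20 else SpacerVariant(site.spacer, f"{len(site.spacer)}-nt")
    designs = []
    for pbs in pbs_range:
        for rtt in rtt_range:
            if not all(_rtt_covers(site, rtt, e.position) for e in all_edits):
                continue
            name = (
                f"{pam_tag} {len(variant)}-nt SE{len(silent_edits)} "
                f"PBS{pbs} RTT{rtt}"
            )
            designs.append(
                PegDesign(
                    site=site,
                    spacer_variant=variant,
                    pbs_len=pbs,
                    rtt_len=rtt,
                    edits=tuple(edits),
                    silent_edits=tuple(silent_edits),
                    name=name,
                )
            )
    return designs


@dataclass(frozen=True)
class SilentEditSet:
    """A ranked set of synonymous substitutions near the corrected base."""

    edits: tuple[EditSpec, ...]
    disrupts_pam: bool
    disrupts_seed: bool
    min_distance_to_target: int


def _translate(seq: str) -> str:
    return str(Seq(seq).translate())


def design_silent_edits(
    seq: str | AmpliconRef,
    frame_offset: int,
    region: tuple[int, int],
    peg_site: GuideSite,
    corrected_position: int,
    max_set_size: int = 3,
) -> list[SilentEditSet]:
    """Synonymous edit sets within ``region`` (typically the RTT span).

    Candidates are single-base substitutions leaving the translation of
    the coding frame (+ strand, first full codon at ``frame_offset``)
    unchanged, excluding the corrected base itself. Sets of 1 to
    ``max_set_size`` edits are verified jointly synonymous and ranked:
    PAM-disrupting first (the pegRNA PAM no longer matches its pattern),
    then protospacer-seed-disrupting (positions 13-20), then proximity
    to the corrected base. If nothing disrupts the PAM, the
    best-available sets are returned with a warning.
    """
    s = seq.sequence if isinstance(seq, AmpliconRef) else seq.upper()
    r0, r1 = region
    # codon-aligned span enclosing the region
    c0 = frame_offset + ((r0 - frame_offset) // 3) * 3
    c1 = frame_offset + (-(-(r1 - frame_offset) // 3)) * 3
    c0 = max(c0, frame_offset)
    c1 = min(c1, frame_offset + ((len(s) - frame_offset) // 3) * 3)
    ref_prot = _translate(s[c0:c1])

    pam_pat = peg_site.pam
    ps, pe = peg_site.pam_interval

    def pam_matches(mutated: str) -> bool:
        pam_seq = mutated[ps:pe]
        if peg_site.strand == "-":
            pam_seq = revcomp(pam_seq)
        return matches_pattern(pam_seq, pam_pat)

    def apply(edits: tuple[EditSpec, ...]) -> str:
        arr = list(s)
        for e in edits:
            arr[e.position] = e.alt
        return "".join(arr)

    singles: list[EditSpec] = []
    for pos in range(max(r0, c0), min(r1, c1)):
        if pos == corrected_position:
            continue
        for alt in "ACGT":
            if alt == s[pos]:
                continue
            e = EditSpec(pos, s[pos], alt, "silent")
            if _translate(apply((e,))[c0:c1]) == ref_prot:
                singles.append(e)

    seed_lo = peg_site.protospacer_position_to_ref(min(SEED_POSITIONS))
    seed_hi = peg_site.protospacer_position_to_ref(max(SEED_POSITIONS))
    seed_interval = (min(seed_lo, seed_hi), max(seed_lo, seed_hi) + 1)

    sets: list[SilentEditSet] = []
    for size in range(1, max_set_size + 1):
        for combo in combinations(singles, size):
            positions = [e.position for e in combo]
            if len(set(positions)) != size:
                continue
            mutated = apply(combo)
            if _translate(mutated[c0:c1]) != ref_prot:
                continue  # edits in one codon may interact non-synonymously
            sets.append(
                SilentEditSet(
                    edits=tuple(sorted(combo, key=lambda e: e.position)),
                    disrupts_pam=not pam_matches(mutated),
                    disrupts_seed=any(
                        seed_interval[0] <= p < seed_interval[1] for p in positions
                    ),
                    min_distance_to_target=min(
                        abs(p - corrected_position) for p in positions
                    ),
                )
            )
    sets.sort(
        key=lambda t: (not t.disrupts_pam, not t.disrupts_seed, t.min_distance_to_target)
    )
    if sets and not any(t.disrupts_pam for t in sets):
        warnings.warn(
            "no synonymous option disrupts the pegRNA PAM; returning best available",
            stacklevel=2,
        )
    return sets


def _guide_matches(guide: GuideSite, seq: str) -> bool:
    f0, f1 = guide.footprint()
    if f0 < 0 or f1 > len(seq):
        return False
    proto = seq[guide.start:guide.end]
    if guide.strand == "-":
        proto = revcomp(proto)
    if proto != guide.spacer:
        return False
    ps, pe = guide.pam_interval
    pam = seq[ps:pe]
    if guide.strand == "-":
        pam = revcomp(pam)
    return matches_pattern(pam, "NGG") or pam == guide.pam or matches_pattern(pam, guide.pam)


def classify_pe3b(ngRNA: GuideSite, ref_seq: str, edited_seq: str) -> str:
    """PE3b iff the ngRNA protospacer+PAM matches only the edited
    sequence (its nick site is created by the edit); PE3 otherwise.
    Raises if the ngRNA matches neither sequence."""
    m_ref = _guide_matches(ngRNA, ref_seq.upper())
    m_edit = _guide_matches(ngRNA, edited_seq.upper())
    if not m_ref and not m_edit:
        raise ValueError("ngRNA matches neither the reference nor the edited sequence")
    return "PE3b" if (m_edit and not m_ref) else "PE3"


@dataclass(frozen=True)
class NickPlan:
    """A secondary-nick plan: ngRNA plus signed inter-nick distance."""

    ngRNA: GuideSite
    distance: int
    nick_class: str  # PE3 | PE3b


def inter_nick_distance(a: GuideSite, b: GuideSite) -> int:
    """Signed nick-to-nick distance, b relative to a, in a's PAM-strand
    orientation. Antisymmetric up to each guide's own orientation."""
    if a.amplicon_id is not None and b.amplicon_id is not None and a.amplicon_id != b.amplicon_id:
        raise ValueError("guides lie on different amplicons")
    d = b.nick_position - a.nick_position
    return d if a.strand == "+" else -d


@dataclass(frozen=True)
class DsgCandidate:
    site: GuideSite
    distance: int
    strand_tag: str  # "PAM" (pegRNA's PAM strand) or "non-PAM"

    @property
    def label(self) -> str:
        return f"{self.distance:+d} {self.strand_tag}"


def enumerate_dsgRNAs(
    seq: str | AmpliconRef,
    peg: GuideSite,
    distance_windows: tuple[tuple[int, int], ...] = DSG_DISTANCE_WINDOWS,
    spacer_lengths: tuple[int, ...] = DSG_SPACER_LENGTHS,
    ngRNA: GuideSite | None = None,
    pam_patterns: list[str] | None = None,
) -> list[DsgCandidate]:
    """All 14-15-nt dead-sgRNA placements whose signed nick-to-nick
    distance from the pegRNA falls in the allowed windows (default
    -60..-30 and +30..+60 bp), excluding candidates overlapping a
    supplied ngRNA footprint. By default no PAM match is required;
    pass ``pam_patterns`` to filter."""
    s = seq.sequence if isinstance(seq, AmpliconRef) else seq.upper()
    amp_id = seq.id if isinstance(seq, AmpliconRef) else None
    ng_fp = ngRNA.footprint() if ngRNA is not None else None
    out: list[DsgCandidate] = []
    for L in spacer_lengths:
        for i in range(len(s) - L + 1):
            for strand in "+-":
                if strand == "+":
                    if i + L + 3 > len(s):
                        continue
                    spacer = s[i:i + L]
                    pam = s[i + L:i + L + 3]
                else:
                    if i - 3 < 0:
                        continue
                    spacer = revcomp(s[i:i + L])
                    pam = revcomp(s[i - 3:i])
                if pam_patterns is not None and not any(
                    matches_pattern(pam, p) for p in pam_patterns
                ):
                    continue
                cand = GuideSite(
                    role="dsgRNA", spacer=spacer, strand=strand, start=i,
                    pam=pam, amplicon_id=amp_id,
                )
                d = inter_nick_distance(peg, cand)
                if not any(lo <= d <= hi for lo, hi in distance_windows):
                    continue
                if ng_fp is not None:
                    c0, c1 = cand.footprint()
                    if c0 < ng_fp[1] and c1 > ng_fp[0]:
                        continue
                out.append(
                    DsgCandidate(
                        site=cand,
                        distance=d,
                        strand_tag="PAM" if strand == peg.strand else "non-PAM",
                    )
                )
    out.sort(key=lambda c: (abs(c.distance), c.site.start, c.site.strand))
    return out
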