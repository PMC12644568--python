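"""Cross-species homology mapping of AS events by local sequence alignment.

Events from each species are matched against mouse-anchored event regions; a
call is accepted when every required region of the candidate covers at least
80% of the corresponding anchor region in the best local alignment.  Events
accepted in at least ten species form the conserved set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from Bio import Align

from splicespan.events_psi import EVENT_TYPES, SpliceEvent

# Region roles that must each reach the coverage threshold, per event type.
# For MX/AF/AL both alternative exons must qualify.
REQUIRED_REGIONS: dict[str, tuple[str, ...]] = {
    "SE": ("alt_exon",),
    "A5": ("alt_segment",),
    "A3": ("alt_segment",),
    "RI": ("retained_intron",),
    "MX": ("alt_exon_1", "alt_exon_2"),
    "AF": ("alt_exon_1", "alt_exon_2"),
    "AL": ("alt_exon_1", "alt_exon_2"),
}


@dataclass
class AnchorRegionSet:
    """The role -> nucleotide sequence map defining one event's alignable
    regions (for the anchor species or any query species)."""

    event_id: str
    event_type: str
    regions: dict[str, str]
    span: int = 0  # total genomic span, used only for tie-breaking

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.event_type}")
        for role, seq in self.regions.items():
            if not seq:
                raise ValueError(f"{self.event_id}: empty sequence for {role}")


@dataclass
class HomologyCall:
    anchor_event_id: str
    target_species: str
    target_event_id: str | None
    region_fractions: dict[str, float]
    accepted: bool


def _make_aligner(
    match: float = 1.0,
    mismatch: float = -2.0,
    gap_open: float = -2.0,
    gap_extend: float = -1.0,
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


_DEFAULT_ALIGNER = _make_aligner()


def align_region(
    query: str, anchor: str, aligner: Align.PairwiseAligner | None = None
) -> float:
    """Fraction of the anchor covered by the best local alignment with the
    query (BLAST-like scoring: match +1, mismatch -2, gap open -2, extend -1).

    Coverage counts anchor positions aligned to query residues in one optimal
    local alignment, divided by the anchor length.
    """
    if not query or not anchor:
        raise ValueError("empty sequence")
    aligner = aligner or _DEFAULT_ALIGNER
    alignments = aligner.align(anchor, query)
    try:
        best = alignments[0]
    except IndexError:
        return 0.0
    if best.score <= 0:
        return 0.0
    anchor_blocks = best.aligned[0]
    covered = int(sum(b - a for a, b in anchor_blocks))
    return covered / len(anchor)


def alignment_score(
    query: str, anchor: str, aligner: Align.PairwiseAligner | None = None
) -> float:
    """Optimal local alignment score under the same scoring as align_region."""
    aligner = aligner or _DEFAULT_ALIGNER
    alignments = aligner.align(anchor, query)
    try:
        return float(alignments.score)
    except (IndexError, AttributeError):
        return 0.0


def match_event(
    anchor: AnchorRegionSet,
    candidates: Sequence[AnchorRegionSet],
    species: str,
    coverage_threshold: float = 0.8,
    aligner: Align.PairwiseAligner | None = None,
) -> HomologyCall:
    """Best homologous counterpart of an anchor event in one species.

    A candidate qualifies when every required region reaches the coverage
    threshold (both alternative exons for MX/AF/AL).  Among qualifying
    candidates the highest mean coverage wins; ties break by smaller genomic
    span, then lexicographic event id.
    """
    required = REQUIRED_REGIONS[anchor.event_type]
    best = None  # (mean_frac, -span, event_id) maximised
    best_fracs: dict[str, float] = {}
    for cand in candidates:
        if cand.event_type != anchor.event_type:
            continue
        fracs = {}
        ok = True
        for role in required:
            if role not in cand.regions or role not in anchor.regions:
                ok = False
                break
            fracs[role] = align_region(
                cand.regions[role], anchor.regions[role], aligner
            )
            if fracs[role] < coverage_threshold:
                ok = False
        if not ok or not fracs:
            continue
        mean_frac = sum(fracs.values()) / len(fracs)
        key = (mean_frac, -cand.span, cand.event_id)
        if best is None or (key[0], key[1]) > (best[0], best[1]) or (
            (key[0], key[1]) == (best[0], best[1]) and key[2] < best[2]
        ):
            best = key
            best_fracs = fracs
    if best is None:
        return HomologyCall(anchor.event_id, species, None, {}, accepted=False)
    return HomologyCall(
        anchor.event_id, species, best[2], best_fracs, accepted=True
    )


def conserved_set(
    calls: Iterable[HomologyCall], min_species: int = 10
) -> set[str]:
    """Anchor events accepted in at least ``min_species`` distinct species."""
    per_event: dict[str, set[str]] = {}
    for call in calls:
        if call.accepted:
            per_event.setdefault(call.anchor_event_id, set()).add(
                call.target_species
            )
    return {ev for ev, sp in per_event.items() if len(sp) >= min_species}


def type_composition(
    events: Sequence[SpliceEvent], conserved: set[str] | None = None
) -> pd.DataFrame:
    """Per-type event counts, fractions, and (when a conserved set is given)
    the within-type conservation rate.  Types with no events report a missing
    rate, not zero."""
    counts = {t: 0 for t in EVENT_TYPES}
    cons = {t: 0 for t in EVENT_TYPES}
    for ev in events:
        counts[ev.event_type] += 1
        if conserved is not None and ev.event_id in conserved:
            cons[ev.event_type] += 1
    total = sum(counts.values())
    rows = []
    for t in EVENT_TYPES:
        frac = counts[t] / total if total else math.nan
        rate = cons[t] / counts[t] if counts[t] else math.nan
        rows.append(
            {
                "event_type": t,
                "count": counts[t],
                "fraction": frac,
                "conserved": cons[t],
                "conservation_rate": rate if conserved is not None else math.nan,
            }
        )
    return pd.DataFrame(rows).set_index("event_type")


def calls_table(calls: Iterable[HomologyCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        row = {
            "anchor_event": c.anchor_event_id,
            "species": c.target_species,
            "target_event": c.target_event_id,
            "accepted": c.accepted,
        }
        for role, frac in c.region_fractions.items():
            row[f"frac_{role}"] = frac
        rows.append(row)
    return pd.DataFrame(rows)
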