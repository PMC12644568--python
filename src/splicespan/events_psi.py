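"""Alternative-splicing event extraction and PSI quantification.

Seven event types are extracted from transcript exon chains by comparing
splice junctions between isoforms of one gene, following the standard
transcript-centric (SUPPA-style) definitions:

* SE  - cassette (skipped) exon
* A5  - alternative 5' splice site (donor shift)
* A3  - alternative 3' splice site (acceptor shift)
* MX  - mutually exclusive exons
* RI  - retained intron
* AF  - alternative first exon
* AL  - alternative last exon

PSI for an event in a sample is the TPM of its inclusion isoforms over the
TPM of inclusion plus exclusion isoforms, times 100.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from splicespan.io_formats import Config, GenomicInterval, TranscriptModel

EVENT_TYPES = ("SE", "A5", "A3", "MX", "RI", "AF", "AL")


@dataclass
class SpliceEvent:
    """One alternative-splicing event with its defining genomic intervals and
    the transcript sets supporting the inclusion and exclusion forms."""

    event_id: str
    gene_id: str
    event_type: str
    defining_intervals: dict[str, GenomicInterval]
    inclusion_transcripts: set[str]
    exclusion_transcripts: set[str]

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.event_type}")
        if not self.inclusion_transcripts or not self.exclusion_transcripts:
            raise ValueError(f"{self.event_id}: empty transcript set")
        if self.inclusion_transcripts & self.exclusion_transcripts:
            raise ValueError(f"{self.event_id}: inclusion/exclusion overlap")
        if self.event_type in ("MX", "AF", "AL"):
            if not {"alt_exon_1", "alt_exon_2"} <= set(self.defining_intervals):
                raise ValueError(f"{self.event_id}: two alternative exons required")

    @property
    def transcripts(self) -> set[str]:
        return self.inclusion_transcripts | self.exclusion_transcripts


def _event_id(
    etype: str, gene: str, chrom: str, strand: str, coords: Iterable[int]
) -> str:
    return f"{etype}:{gene}:{chrom}:{'-'.join(str(c) for c in coords)}:{strand}"


def _junctions(t: TranscriptModel) -> list[tuple[int, int]]:
    return [(a.end, b.start) for a, b in zip(t.exons, t.exons[1:])]


def extract_events(models: Iterable[TranscriptModel]) -> list[SpliceEvent]:
    """Extract all seven AS event types from a collection of transcripts.

    Events are found per gene by pairwise junction comparison; the supporting
    inclusion/exclusion transcript sets are then recomputed over *all*
    transcripts of the gene, so they are independent of which pair first
    revealed the event.  Genes with fewer than two transcripts yield nothing.
    """
    by_gene: dict[str, list[TranscriptModel]] = {}
    for m in models:
        by_gene.setdefault(m.gene_id, []).append(m)

    events: dict[str, SpliceEvent] = {}
    for gene, txs in sorted(by_gene.items()):
        if len(txs) < 2:
            continue
        txs = sorted(txs, key=lambda t: t.transcript_id)
        for ev in _gene_events(gene, txs):
            events.setdefault(ev.event_id, ev)
    return sorted(events.values(), key=lambda e: e.event_id)


def _gene_events(gene: str, txs: list[TranscriptModel]) -> list[SpliceEvent]:
    chrom, strand = txs[0].chrom, txs[0].strand
    juncs = {t.transcript_id: set(_junctions(t)) for t in txs}
    exon_sets = {
        t.transcript_id: {(e.start, e.end) for e in t.exons} for t in txs
    }
    tids = [t.transcript_id for t in txs]

    def with_junc(j: tuple[int, int]) -> set[str]:
        return {tid for tid in tids if j in juncs[tid]}

    def with_juncs(*js: tuple[int, int]) -> set[str]:
        return {tid for tid in tids if all(j in juncs[tid] for j in js)}

    def make(etype, coords, intervals, inc, exc):
        inc, exc = set(inc), set(exc)
        both = inc & exc
        inc -= both
        exc -= both
        if not inc or not exc:
            return None
        return SpliceEvent(
            event_id=_event_id(etype, gene, chrom, strand, coords),
            gene_id=gene,
            event_type=etype,
            defining_intervals=intervals,
            inclusion_transcripts=inc,
            exclusion_transcripts=exc,
        )

    out: list[SpliceEvent] = []

    # SE: exon triple e1-e2-e3 vs direct junction e1.end -> e3.start
    for t in txs:
        for i in range(1, len(t.exons) - 1):
            e1, e2, e3 = t.exons[i - 1], t.exons[i], t.exons[i + 1]
            skip = (e1.end, e3.start)
            if not with_junc(skip):
                continue
            inc = with_juncs((e1.end, e2.start), (e2.end, e3.start))
            ev = make(
                "SE",
                (e1.end, e2.start, e2.end, e3.start),
                {"alt_exon": e2, "upstream_exon": e1, "downstream_exon": e3},
                inc,
                with_junc(skip),
            )
            if ev:
                out.append(ev)

    # RI: single exon spanning s1..e2 vs junction (e1, s2) flanked by exons
    # with matching outer boundaries s1 and e2
    for t in txs:
        for a, b in zip(t.exons, t.exons[1:]):
            s1, e1, s2, e2 = a.start, a.end, b.start, b.end
            retaining = {
                tid for tid in tids if (s1, e2) in exon_sets[tid]
            }
            if not retaining:
                continue
            exc = with_junc((e1, s2))
            ev = make(
                "RI",
                (s1, e1, s2, e2),
                {
                    "retained_intron": GenomicInterval(chrom, e1, s2, strand),
                    "upstream_exon": a,
                    "downstream_exon": b,
                },
                retaining,
                exc,
            )
            if ev:
                out.append(ev)

    # A5/A3: junctions sharing one boundary, overlapping alternative exons.
    all_juncs = sorted({j for js in juncs.values() for j in js})
    by_start: dict[int, list[int]] = {}
    by_end: dict[int, list[int]] = {}
    for e, s in all_juncs:
        by_start.setdefault(s, []).append(e)
        by_end.setdefault(e, []).append(s)

    def _exon_with_end(t: TranscriptModel, end: int) -> GenomicInterval | None:
        for e in t.exons:
            if e.end == end:
                return e
        return None

    def _exon_with_start(t: TranscriptModel, start: int) -> GenomicInterval | None:
        for e in t.exons:
            if e.start == start:
                return e
        return None

    # variation on the left side of the intron (same acceptor s, donors differ
    # on + strand => A5; on - strand this is the acceptor side => A3)
    for s, ends in by_start.items():
        ends = sorted(set(ends))
        for i in range(len(ends)):
            for j in range(i + 1, len(ends)):
                e_short, e_long = ends[i], ends[j]
                # the two left exons must overlap (a shifted splice site, not
                # a distinct exon)
                exons_short = [
                    x
                    for t in txs
                    if (e_short, s) in juncs[t.transcript_id]
                    and (x := _exon_with_end(t, e_short))
                ]
                exons_long = [
                    x
                    for t in txs
                    if (e_long, s) in juncs[t.transcript_id]
                    and (x := _exon_with_end(t, e_long))
                ]
                if not any(
                    a.overlaps(b) for a in exons_short for b in exons_long
                ):
                    continue
                etype = "A5" if strand == "+" else "A3"
                diff = GenomicInterval(chrom, e_short, e_long, strand)
                ev = make(
                    etype,
                    (e_short, e_long, s),
                    {"alt_segment": diff},
                    with_junc((e_long, s)),  # longer exon = inclusion
                    with_junc((e_short, s)),
                )
                if ev:
                    out.append(ev)

    # variation on the right side of the intron (same donor e on + strand;
    # acceptors differ => A3 on +, A5 on -)
    for e, starts in by_end.items():
        starts = sorted(set(starts))
        for i in range(len(starts)):
            for j in range(i + 1, len(starts)):
                s_long, s_short = starts[i], starts[j]  # smaller start = longer exon
                exons_long = [
                    x
                    for t in txs
                    if (e, s_long) in juncs[t.transcript_id]
                    and (x := _exon_with_start(t, s_long))
                ]
                exons_short = [
                    x
                    for t in txs
                    if (e, s_short) in juncs[t.transcript_id]
                    and (x := _exon_with_start(t, s_short))
                ]
                if not any(
                    a.overlaps(b) for a in exons_long for b in exons_short
                ):
                    continue
                etype = "A3" if strand == "+" else "A5"
                diff = GenomicInterval(chrom, s_long, s_short, strand)
                ev = make(
                    etype,
                    (e, s_long, s_short),
                    {"alt_segment": diff},
                    with_junc((e, s_long)),
                    with_junc((e, s_short)),
                )
                if ev:
                    out.append(ev)

    # MX: two non-overlapping middle exons sharing both flanking junction
    # boundaries
    middles: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for t in txs:
        for i in range(1, len(t.exons) - 1):
            e1, em, e3 = t.exons[i - 1], t.exons[i], t.exons[i + 1]
            middles.setdefault((e1.end, e3.start), []).append((em.start, em.end))
    for (left, right), mids in middles.items():
        mids = sorted(set(mids))
        for i in range(len(mids)):
            for j in range(i + 1, len(mids)):
                (s_a, e_a), (s_b, e_b) = mids[i], mids[j]
                if e_a > s_b:  # must not overlap
                    continue
                exon_a = GenomicInterval(chrom, s_a, e_a, strand)
                exon_b = GenomicInterval(chrom, s_b, e_b, strand)
                inc = with_juncs((left, s_a), (e_a, right))
                exc = with_juncs((left, s_b), (e_b, right))
                # transcripts containing both middle exons in one chain are
                # not mutually exclusive usage; drop them via make()
                ev = make(
                    "MX",
                    (left, s_a, e_a, s_b, e_b, right),
                    {"alt_exon_1": exon_a, "alt_exon_2": exon_b},
                    inc,
                    exc,
                )
                if ev:
                    out.append(ev)

    # AF/AL: distinct terminal exons splicing into the same downstream /
    # upstream exon.  "First" and "last" are strand-aware.
    def terminal_pairs(first: bool):
        """Yield (terminal_exon, junction) per transcript at the 5' (first)
        or 3' (last) end of the mRNA."""
        res = {}
        for t in txs:
            if len(t.exons) < 2:
                continue
            if (t.strand == "+") == first:
                term = t.exons[0]
                junc = (t.exons[0].end, t.exons[1].start)
                shared = junc[1]  # shared downstream acceptor
                side = "left"
            else:
                term = t.exons[-1]
                junc = (t.exons[-2].end, t.exons[-1].start)
                shared = junc[0]
                side = "right"
            res[t.transcript_id] = (term, junc, shared, side)
        return res

    for first, etype in ((True, "AF"), (False, "AL")):
        terms = terminal_pairs(first)
        by_shared: dict[tuple[int, str], list[str]] = {}
        for tid, (_, _, shared, side) in terms.items():
            by_shared.setdefault((shared, side), []).append(tid)
        for (shared, side), tids_here in by_shared.items():
            variants: dict[tuple[int, int], set[str]] = {}
            for tid in tids_here:
                term, junc, _, _ = terms[tid]
                variants.setdefault((term.start, term.end), set()).add(tid)
            keys = sorted(variants)
            for i in range(len(keys)):
                for j in range(i + 1, len(keys)):
                    (s_a, e_a), (s_b, e_b) = keys[i], keys[j]
                    if e_a > s_b:  # alternative terminal exons must not overlap
                        continue
                    exon_a = GenomicInterval(chrom, s_a, e_a, strand)
                    exon_b = GenomicInterval(chrom, s_b, e_b, strand)
                    # inclusion = the distal variant (farther from the gene
                    # body): on the left side that is the lower-coordinate exon
                    inc_key, exc_key = (
                        (keys[i], keys[j]) if side == "left" else (keys[j], keys[i])
                    )
                    ev = make(
                        etype,
                        (s_a, e_a, s_b, e_b, shared),
                        {"alt_exon_1": exon_a, "alt_exon_2": exon_b},
                        variants[inc_key],
                        variants[exc_key],
                    )
                    if ev:
                        out.append(ev)

    return out


# ---------------------------------------------------------------------------
# PSI


def compute_psi(
    event: SpliceEvent, tpm: pd.DataFrame, sample: str
) -> float:
    """PSI of an event in one sample from transcript TPMs.

    PSI = 100 * sum(TPM inclusion) / sum(TPM inclusion + exclusion);
    NaN when the denominator is zero.  All of the event's transcripts must be
    present in the table.
    """
    for tid in event.transcripts:
        if tid not in tpm.index:
            raise KeyError(f"transcript {tid!r} absent from expression table")
    inc = float(tpm.loc[sorted(event.inclusion_transcripts), sample].sum())
    exc = float(tpm.loc[sorted(event.exclusion_transcripts), sample].sum())
    denom = inc + exc
    if denom == 0:
        return math.nan
    return 100.0 * inc / denom


def psi_matrix(
    events: Iterable[SpliceEvent], tpm: pd.DataFrame
) -> pd.DataFrame:
    """Events x samples PSI matrix (vectorised over samples)."""
    rows = {}
    for ev in events:
        for tid in ev.transcripts:
            if tid not in tpm.index:
                raise KeyError(f"transcript {tid!r} absent from expression table")
        inc = tpm.loc[sorted(ev.inclusion_transcripts)].sum(axis=0)
        tot = inc + tpm.loc[sorted(ev.exclusion_transcripts)].sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            rows[ev.event_id] = 100.0 * inc / tot.where(tot > 0)
    return pd.DataFrame(rows).T


def aggregate_species_psi(
    sample_psi: pd.DataFrame,
    sample_to_species_tissue: Mapping[str, tuple[str, str]],
) -> dict[str, pd.DataFrame]:
    """Collapse a per-sample PSI matrix into per-tissue species matrices.

    A species' value is the unweighted mean of its non-missing sample PSIs;
    missing when every sample is missing.
    """
    for s in sample_psi.columns:
        if s not in sample_to_species_tissue:
            raise KeyError(f"sample {s!r} has no (species, tissue) mapping")
    tissues = sorted({t for _, t in sample_to_species_tissue.values()})
    out = {}
    for tissue in tissues:
        cols = [
            s
            for s in sample_psi.columns
            if sample_to_species_tissue[s][1] == tissue
        ]
        groups = pd.Series(
            {s: sample_to_species_tissue[s][0] for s in cols}
        )
        out[tissue] = sample_psi[cols].T.groupby(groups).mean().T
    return out


def filter_events(
    psi: pd.DataFrame,
    gene_tpm: pd.DataFrame,
    event_genes: Mapping[str, str],
    config: Config | None = None,
) -> list[str]:
    """Apply the expression/variability/coverage filters.

    An event is retained iff (a) its gene has TPM > ``tpm_cutoff`` in at
    least ceil(n_samples * tpm_sample_fraction) samples, (b) the range of its
    non-missing PSI values is >= ``psi_range_cutoff``, and (c) it has
    non-missing PSI in >= ``min_species`` units.
    """
    config = config or Config()
    n_samples = gene_tpm.shape[1]
    min_expressed = math.ceil(n_samples * config.tpm_sample_fraction)
    retained = []
    for event_id in psi.index:
        gene = event_genes[event_id]
        if gene not in gene_tpm.index:
            continue
        expressed = int((gene_tpm.loc[gene] > config.tpm_cutoff).sum())
        if expressed < min_expressed:
            continue
        vals = psi.loc[event_id].dropna()
        if len(vals) < config.min_species:
            continue
        if len(vals) == 0 or vals.max() - vals.min() < config.psi_range_cutoff:
            continue
        retained.append(event_id)
    return retained
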