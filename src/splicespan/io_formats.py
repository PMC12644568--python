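"""Readers and writers for the external formats the pipeline consumes.

All genomic coordinates are held internally as 0-based half-open intervals;
1-based inclusive dialects (GTF) are converted at the boundary.  PSI values are
on the 0-100 (percent) scale and missingness is explicit (NA), never zero.
Every table written by the pipeline carries a comment header recording the
tool version, a hash of the configuration, and the random seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import dendropy
import numpy as np
import pandas as pd

IUPAC_CODES = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse-complement an uppercase ACGTN nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open stranded interval."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end {self.end} must exceed start {self.start}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class TranscriptModel:
    """A transcript as an ordered chain of exons on one chromosome/strand."""

    transcript_id: str
    gene_id: str
    exons: list[GenomicInterval]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: no exons")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValueError(f"{self.transcript_id}: exons span chrom/strand")
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(f"{self.transcript_id}: overlapping exons")

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def introns(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(self.chrom, a.end, b.start, self.strand)
            for a, b in zip(self.exons, self.exons[1:])
        ]


@dataclass
class Config:
    """Thresholds, resampling counts, and the seed for one pipeline run.

    Defaults follow the study design: |rho| > 0.4 with BH-FDR < 0.05 declares
    a trait association significant, events need a PSI range >= 20 and gene
    TPM > 0.5 in at least a third of samples, homologs in >= 10 species, and
    alignment coverage >= 0.8 of the anchor region.
    """

    rho_cutoff: float = 0.4
    fdr_cutoff: float = 0.05
    psi_range_cutoff: float = 20.0
    tpm_cutoff: float = 0.5
    tpm_sample_fraction: float = 1.0 / 3.0
    min_species: int = 10
    alignment_coverage: float = 0.8
    contrast_cutoff: float = 0.2
    n_resample: int = 500
    n_permutations: int = 500
    n_overlap_samplings: int = 10000
    exon_flank: int = 100
    intron_flank: int = 50
    enrichment_fdr: float = 0.15
    elastic_net_l1_ratio: float = 0.5
    cv_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.fdr_cutoff <= 1:
            raise ValueError("fdr_cutoff outside [0,1]")
        if not 0 <= self.rho_cutoff <= 1:
            raise ValueError("rho_cutoff outside [0,1]")
        if not 0 <= self.psi_range_cutoff <= 100:
            raise ValueError("psi_range_cutoff outside [0,100]")
        if self.min_species < 2:
            raise ValueError("min_species must be >= 2")
        if not 0 < self.alignment_coverage <= 1:
            raise ValueError("alignment_coverage outside (0,1]")

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# GTF

_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_gtf_attributes(text: str) -> dict[str, str]:
    return dict(_GTF_ATTR.findall(text))


def read_gtf(path: str | Path) -> list[TranscriptModel]:
    """Read exon features from a GTF file into transcript models.

    GTF 1-based inclusive coordinates are converted to 0-based half-open.
    Non-exon features are ignored.  Malformed lines raise with their line
    number; an exon feature without a ``transcript_id`` attribute is an error.
    """
    exons: dict[str, list[GenomicInterval]] = {}
    genes: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(
                    f"{path}:{lineno}: expected 9 tab-separated fields, got {len(fields)}"
                )
            chrom, _, feature, start, end, _, strand, _, attrs = fields
            if feature != "exon":
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            attributes = _parse_gtf_attributes(attrs)
            if "transcript_id" not in attributes:
                raise ValueError(f"{path}:{lineno}: exon without transcript_id")
            tid = attributes["transcript_id"]
            gid = attributes.get("gene_id", tid)
            exons.setdefault(tid, []).append(
                GenomicInterval(chrom, start_i - 1, end_i, strand)
            )
            genes[tid] = gid
    return [
        TranscriptModel(transcript_id=tid, gene_id=genes[tid], exons=ivs)
        for tid, ivs in exons.items()
    ]


def write_gtf(models: Iterable[TranscriptModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in models:
            for iv in m.exons:
                attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'
                fh.write(
                    f"{iv.chrom}\tsplicespan\texon\t{iv.start + 1}\t{iv.end}\t.\t"
                    f"{iv.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# Newick


def read_newick(path: str | Path) -> dendropy.Tree:
    """Read a single rooted tree; every edge must carry a branch length and
    tip labels must be unique."""
    from dendropy.dataio.newickreader import NewickReader

    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", suppress_internal_node_taxa=True
        )
    except NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise ValueError(f"duplicate tip labels in tree: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate tip labels in tree")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise ValueError("tree edge without branch length")
        if edge.length < 0:
            raise ValueError("negative branch length")
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


# ---------------------------------------------------------------------------
# PSI / generic tables


def output_header(config: Config | None = None, seed: int | None = None) -> str:
    from splicespan import __version__

    chash = config.hash() if config is not None else "none"
    s = seed if seed is not None else (config.seed if config is not None else "none")
    return (
        f"# splicespan v{__version__}\n"
        f"# config_hash: {chash}\n"
        f"# seed: {s}\n"
    )


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    config: Config | None = None,
    seed: int | None = None,
    index: bool = True,
) -> None:
    """Write a TSV with the standard provenance comment header."""
    with open(path, "w") as fh:
        fh.write(output_header(config, seed))
        df.to_csv(fh, sep="\t", na_rep="NA", index=index)


def read_table(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", comment="#", index_col=index_col, na_values=["NA"]
    )


def read_psi_table(path: str | Path) -> pd.DataFrame:
    """Read an events x units PSI matrix; values must lie in [0,100] or be NA."""
    df = read_table(path, index_col=0)
    if df.index.duplicated().any():
        raise ValueError("duplicate event identifiers in PSI table")
    if df.columns.duplicated().any():
        raise ValueError("duplicate unit identifiers in PSI table")
    values = df.to_numpy(dtype=float)
    bad = np.argwhere((values < 0) | (values > 100))
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"PSI value {values[i, j]} outside [0,100] at "
            f"event {df.index[i]!r}, unit {df.columns[j]!r}"
        )
    return df


def write_psi_table(
    psi: pd.DataFrame, path: str | Path, config: Config | None = None
) -> None:
    write_table(psi, path, config=config)


# ---------------------------------------------------------------------------
# FASTA (plain sequential; sequences here are short event regions)


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# Motifs, gene sets, regions


@dataclass
class Motif:
    """One RBP binding motif: IUPAC consensus, or a PWM with a score threshold
    expressed as a fraction of the maximum attainable score."""

    name: str
    consensus: str | None = None
    pwm: np.ndarray | None = None  # shape (length, 4), columns A,C,G,T
    threshold: float = 0.8

    def __post_init__(self) -> None:
        if (self.consensus is None) == (self.pwm is None):
            raise ValueError("motif needs exactly one of consensus or PWM")
        if self.consensus is not None:
            bad = set(self.consensus.upper()) - set(IUPAC_CODES)
            if bad:
                raise ValueError(
                    f"motif {self.name}: non-IUPAC characters {sorted(bad)}"
                )
            if len(self.consensus) < 4:
                raise ValueError(f"motif {self.name}: length < 4")
        else:
            sums = self.pwm.sum(axis=1)
            off = np.abs(sums - 1.0)
            if (off > 1e-6).any():
                pos = int(np.argmax(off))
                raise ValueError(
                    f"motif {self.name}: PWM column {pos} sums to {sums[pos]:.6f}"
                )
            if self.pwm.shape[0] < 4:
                raise ValueError(f"motif {self.name}: length < 4")
            if not 0 < self.threshold <= 1:
                raise ValueError("PWM threshold outside (0,1]")

    def __len__(self) -> int:
        return len(self.consensus) if self.consensus is not None else self.pwm.shape[0]


MotifSet = dict[str, list[Motif]]


def read_motifs(path: str | Path) -> MotifSet:
    """Read RBP motifs.

    Two dialects are accepted: a MEME-like file with ``MOTIF <name>`` blocks
    followed by ``letter-probability matrix`` rows (A C G T order), and a
    plain two-column table of ``<rbp> <IUPAC consensus>`` lines.
    """
    text = Path(path).read_text()
    motifs: MotifSet = {}
    if "MOTIF" in text:
        blocks = re.split(r"^MOTIF\s+", text, flags=re.M)[1:]
        for block in blocks:
            lines = block.strip().splitlines()
            name = lines[0].split()[0]
            rows = []
            for line in lines[1:]:
                parts = line.split()
                if len(parts) == 4 and all(
                    re.fullmatch(r"[\d.eE+-]+", p) for p in parts
                ):
                    rows.append([float(p) for p in parts])
            if not rows:
                raise ValueError(f"MOTIF {name}: no probability matrix rows")
            motifs.setdefault(name, []).append(
                Motif(name=name, pwm=np.asarray(rows, dtype=float))
            )
    else:
        for lineno, line in enumerate(text.splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected '<rbp> <consensus>'")
            name, consensus = parts
            motifs.setdefault(name, []).append(
                Motif(name=name, consensus=consensus.upper().replace("U", "T"))
            )
    return motifs


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT gene-set collection: set name, description, then genes."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def read_regions(path: str | Path) -> list[GenomicInterval]:
    """Read a BED-like TSV (chrom, start, end[, name, score, strand]) of
    0-based half-open intervals, e.g. IDP-region projections."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: need chrom/start/end")
            strand = parts[5] if len(parts) > 5 and parts[5] in "+-" else "+"
            out.append(
                GenomicInterval(parts[0], int(parts[1]), int(parts[2]), strand)
            )
    return out
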