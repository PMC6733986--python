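"""Readers, writers and core data containers.

Standard formats are delegated to established libraries: MatrixMarket via
:mod:`scipy.io`, FASTA via Biopython, tables via pandas.  The containers are
light dataclasses validating the invariants the pipeline relies on
(non-negative counts, unique identifiers, consistent dimensions).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class ConfigurationError(ValueError):
    """Raised for invalid configurations or degenerate inputs."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        raise ConfigurationError(f"duplicate {what} identifiers")


@dataclass
class CountMatrix:
    """Genes x cells raw UMI counts with identifiers."""

    values: np.ndarray  # (n_genes, n_cells) non-negative integers
    gene_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ConfigurationError("count matrix must be 2-D")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ConfigurationError(
                "count matrix shape inconsistent with identifier lists"
            )
        if np.any(self.values < 0):
            raise ConfigurationError("negative entries in count matrix")
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.cell_ids, "cell")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)


@dataclass
class BulkExpressionMatrix:
    """Features x samples non-negative bulk expression with group labels.

    ``feature_to_gene`` (optional) maps measurement features (e.g. CAGE TSS
    peaks) many-to-one onto genes; :func:`keranet.screen.aggregate_features_to_genes`
    collapses it.
    """

    values: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]
    sample_group: dict[str, str]
    feature_to_gene: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ConfigurationError("bulk matrix shape inconsistent with ids")
        if np.any(self.values < 0):
            raise ConfigurationError("negative bulk expression values")
        _check_unique(self.feature_ids, "feature")
        _check_unique(self.sample_ids, "sample")
        missing = set(self.sample_ids) - set(self.sample_group)
        if missing:
            raise ConfigurationError(f"samples without group label: {sorted(missing)[:5]}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)


@dataclass
class SERegion:
    """One super-enhancer interval; 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    region_id: str
    state: str  # "BK" or "DK"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ConfigurationError(f"region {self.region_id}: end <= start")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SERegionSet:
    """State-labelled super-enhancer regions with their sequences."""

    regions: list[SERegion]
    sequences: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_unique([r.region_id for r in self.regions], "region")
        for r in self.regions:
            seq = self.sequences.get(r.region_id)
            if seq is not None and len(seq) != r.length:
                raise ConfigurationError(
                    f"region {r.region_id}: sequence length != end - start"
                )

    def by_state(self, state: str) -> list[SERegion]:
        return [r for r in self.regions if r.state == state]

    @property
    def states(self) -> list[str]:
        return sorted({r.state for r in self.regions})


# ---------------------------------------------------------------------------
# single-cell counts


def write_mtx_triplet(counts: CountMatrix, outdir: str | Path) -> None:
    """Write the CellRanger-style triplet: matrix.mtx, genes.tsv, barcodes.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(outdir / "matrix.mtx", scipy.sparse.csc_matrix(counts.values))
    pd.Series(counts.gene_ids).to_csv(
        outdir / "genes.tsv", sep="\t", header=False, index=False
    )
    pd.Series(counts.cell_ids).to_csv(
        outdir / "barcodes.tsv", sep="\t", header=False, index=False
    )


def read_mtx_triplet(indir: str | Path) -> CountMatrix:
    indir = Path(indir)
    values = scipy.io.mmread(indir / "matrix.mtx").toarray().astype(np.int64)
    genes = pd.read_csv(indir / "genes.tsv", sep="\t", header=None)[0].astype(str).tolist()
    cells = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0].astype(str).tolist()
    return CountMatrix(values, genes, cells)


def write_counts_tsv(counts: CountMatrix, path: str | Path) -> None:
    counts.to_frame().to_csv(path, sep="\t")


def read_counts_tsv(path: str | Path) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CountMatrix(
        df.to_numpy().astype(np.int64),
        [str(g) for g in df.index],
        [str(c) for c in df.columns],
    )


# ---------------------------------------------------------------------------
# bulk matrix


def write_bulk_tsv(bulk: BulkExpressionMatrix, path: str | Path, annot_path: str | Path) -> None:
    bulk.to_frame().to_csv(path, sep="\t")
    annot = pd.DataFrame(
        {
            "sample_id": bulk.sample_ids,
            "cell_type": [bulk.sample_group[s] for s in bulk.sample_ids],
        }
    )
    annot.to_csv(annot_path, sep="\t", index=False)


def read_bulk_tsv(
    path: str | Path,
    annot_path: str | Path,
    feature_to_gene: Mapping[str, str] | None = None,
) -> BulkExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    annot = pd.read_csv(annot_path, sep="\t")
    group = dict(zip(annot["sample_id"].astype(str), annot["cell_type"].astype(str)))
    return BulkExpressionMatrix(
        df.to_numpy(dtype=float),
        [str(f) for f in df.index],
        [str(s) for s in df.columns],
        group,
        dict(feature_to_gene) if feature_to_gene is not None else None,
    )


# ---------------------------------------------------------------------------
# super-enhancer regions


def write_se_regions(se: SERegionSet, bed_path: str | Path, fasta_path: str | Path) -> None:
    """BED6 (name = region id, score 0, strand '.') + FASTA keyed by region id."""
    with open(bed_path, "w") as fh:
        for r in se.regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.region_id}\t0\t.\n")
    records = [
        SeqRecord(Seq(se.sequences[r.region_id]), id=r.region_id, description=f"state={r.state}")
        for r in se.regions
        if r.region_id in se.sequences
    ]
    SeqIO.write(records, str(fasta_path), "fasta")


def read_se_regions(
    bed_path: str | Path,
    fasta_path: str | Path,
    state_of: Mapping[str, str] | None = None,
) -> SERegionSet:
    """Read BED6 + FASTA.

    State labels are taken from ``state_of`` (region id -> state) when given,
    else parsed from a ``state=XX`` token in the FASTA description.
    """
    states: dict[str, str] = dict(state_of or {})
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        sequences[rec.id] = str(rec.seq).upper()
        if rec.id not in states:
            for token in rec.description.split():
                if token.startswith("state="):
                    states[rec.id] = token.split("=", 1)[1]
    regions = []
    with open(bed_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.rstrip("\n").split("\t")
            chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
            regions.append(SERegion(chrom, start, end, name, states.get(name, "NA")))
    return SERegionSet(regions, sequences)


# ---------------------------------------------------------------------------
# gene lists / GMT / JSON


def read_gene_list(path: str | Path) -> list[str]:
    """One symbol per line; blank lines and '#' comments ignored."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """GMT: set name, description, then member genes, tab separated."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) >= 3:
                sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_json(obj, path: str | Path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=default)


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
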