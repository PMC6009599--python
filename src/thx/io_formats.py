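"""Readers and writers for every external representation the pipeline touches.

The pipeline consumes simplified two-channel probe tables (one TSV per
array, sample channel vs genomic-DNA reference channel), a sample metadata
TSV, and a genome as FASTA + GFF3.  It emits plain TSV result tables.  The
probe table is a deliberately minimal dialect of an Agilent Feature
Extraction export: only the processed sample/reference signals, a
probe-to-gene mapping and a control flag are retained, because nothing
downstream needs more.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

log = logging.getLogger(__name__)

FRACTIONS = ("total", "monosome", "polysome")
START_CODONS = ("ATG", "GTG", "TTG")
STOP_CODONS = ("TAA", "TAG", "TGA")

PROBE_COLUMNS = ("probe_id", "gene_id", "is_control", "signal", "reference")


class FormatError(ValueError):
    """An input file does not match its documented layout."""


@dataclass(frozen=True)
class ArraySample:
    """One hybridized array: which RNA pool, at which temperature, which culture.

    The normalization batch is a pure function of the fraction: total-RNA
    arrays form one batch, monosome- and polysome-associated arrays the
    other, because the two pools have different intensity distributions.
    """

    sample_id: str
    fraction: str
    temperature_c: int
    replicate: int

    def __post_init__(self) -> None:
        if self.fraction not in FRACTIONS:
            raise ValueError(f"unknown fraction {self.fraction!r}; expected one of {FRACTIONS}")
        if self.temperature_c not in (30, 42):
            raise ValueError(f"temperature must be 30 or 42, got {self.temperature_c}")
        if self.replicate < 1:
            raise ValueError(f"replicate must be >= 1, got {self.replicate}")

    @property
    def batch(self) -> str:
        return "total" if self.fraction == "total" else "ribosomal"

    @property
    def design_key(self) -> tuple[str, int, int]:
        return (self.fraction, self.temperature_c, self.replicate)


@dataclass
class ProbeTable:
    """Per-array probe rows plus the array's sample annotation.

    ``data`` columns: probe_id, gene_id (empty string = unmapped),
    is_control (bool), signal, reference.  Signals may be negative:
    background subtraction in feature extraction can push processed
    intensities below zero, and the GEM construction rules handle that.
    """

    data: pd.DataFrame
    sample: ArraySample

    def __post_init__(self) -> None:
        missing = [c for c in PROBE_COLUMNS if c not in self.data.columns]
        if missing:
            raise FormatError(f"missing column: {missing[0]}")
        if self.data["probe_id"].duplicated().any():
            dup = self.data.loc[self.data["probe_id"].duplicated(), "probe_id"].iloc[0]
            raise FormatError(f"duplicate probe_id {dup!r} in array {self.sample.sample_id}")
        ctrl = self.data["is_control"].astype(bool)
        if (self.data.loc[ctrl, "gene_id"].astype(str) != "").any():
            raise FormatError("control probes must have an empty gene_id")

    def __len__(self) -> int:
        return len(self.data)


_TRUTHY = {"1", "true", "yes", "t"}
_FALSY = {"0", "false", "no", "f", ""}


def _parse_bool_column(col: pd.Series, path: Path) -> pd.Series:
    vals = col.astype(str).str.strip().str.lower()
    bad = ~vals.isin(_TRUTHY | _FALSY)
    if bad.any():
        row = int(bad.idxmax()) + 2  # +1 header, +1 one-based
        raise FormatError(f"{path}: unparseable is_control value at row {row}")
    return vals.isin(_TRUTHY)


def _parse_numeric_column(col: pd.Series, name: str, path: Path) -> pd.Series:
    vals = col.astype(str).str.strip()
    try:
        # numpy's parser is correctly rounded, so repr-format round-trips exactly
        return pd.Series(np.asarray(vals, dtype=float), index=col.index)
    except ValueError:
        for i, v in enumerate(vals):
            try:
                float(v)
            except ValueError:
                raise FormatError(f"{path}: non-numeric {name} at row {i + 2}") from None
        raise


def read_probe_table(path: str | Path, sample_meta: ArraySample) -> ProbeTable:
    """Read one per-array probe TSV, preserving row order.

    Negative intensities are legal and retained; the negative-value rules
    are applied later, during log-ratio formation.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, na_values=[])
    for col in PROBE_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing column: {col}")
    df = df.reset_index(drop=True)
    out = pd.DataFrame(
        {
            "probe_id": df["probe_id"].astype(str),
            "gene_id": df["gene_id"].astype(str),
            "is_control": _parse_bool_column(df["is_control"], path),
            "signal": _parse_numeric_column(df["signal"], "signal", path),
            "reference": _parse_numeric_column(df["reference"], "reference", path),
        }
    )
    return ProbeTable(out, sample_meta)


def write_probe_table(table: ProbeTable, path: str | Path) -> None:
    df = table.data.copy()
    df["is_control"] = df["is_control"].astype(bool).map({True: "true", False: "false"})
    df["signal"] = df["signal"].map(repr)
    df["reference"] = df["reference"].map(repr)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_sample_metadata(path: str | Path) -> list[ArraySample]:
    """Read the experiment design TSV (sample_id, fraction, temperature_c, replicate)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("sample_id", "fraction", "temperature_c", "replicate"):
        if col not in df.columns:
            raise FormatError(f"missing column: {col}")
    samples = [
        ArraySample(r.sample_id, r.fraction, int(r.temperature_c), int(r.replicate))
        for r in df.itertuples()
    ]
    keys = [s.design_key for s in samples]
    if len(set(keys)) != len(keys):
        raise FormatError(f"{path}: duplicate (fraction, temperature, replicate) design entry")
    return samples


def write_sample_metadata(samples: Sequence[ArraySample], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "fraction": [s.fraction for s in samples],
            "temperature_c": [s.temperature_c for s in samples],
            "replicate": [s.replicate for s in samples],
        }
    )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# Genome


@dataclass(frozen=True)
class CDSRecord:
    """One protein-coding gene in coding orientation.

    ``cds`` runs 5'->3' from the start codon through the stop codon;
    ``upstream50`` is the <=50 nt immediately 5' of the start codon on the
    coding strand (shorter only at contig edges); ``protein`` is the
    standard-table translation of the CDS with the terminal stop removed.
    """

    gene_id: str
    strand: str
    cds: str
    upstream50: str
    protein: str
    is_pseudogene: bool = False
    frame_ok: bool = True

    @classmethod
    def from_sequence(
        cls,
        gene_id: str,
        strand: str,
        cds: str,
        upstream50: str,
        is_pseudogene: bool = False,
    ) -> "CDSRecord":
        cds = cds.upper()
        upstream50 = upstream50.upper()
        frame_ok = len(cds) % 3 == 0
        if not frame_ok:
            warnings.warn(f"{gene_id}: CDS length {len(cds)} not divisible by 3")
        if len(cds) >= 3 and cds[:3] not in START_CODONS:
            warnings.warn(f"{gene_id}: non-canonical start codon {cds[:3]}")
        trimmed = cds[: 3 * (len(cds) // 3)]
        if len(trimmed) >= 3 and trimmed[-3:] not in STOP_CODONS:
            warnings.warn(f"{gene_id}: non-canonical stop codon {trimmed[-3:]}")
        protein = str(Seq(trimmed).translate())
        if protein.endswith("*"):
            protein = protein[:-1]
        return cls(gene_id, strand, cds, upstream50, protein, is_pseudogene, frame_ok)

    @property
    def start_codon(self) -> str:
        return self.cds[:3]

    @property
    def stop_codon(self) -> str:
        return self.cds[-3:] if self.frame_ok else ""


def _feature_gene_id(feature) -> str:
    for key in ("locus_tag", "gene_id", "Parent", "ID"):
        if key in feature.attributes:
            val = feature.attributes[key][0]
            return val.removeprefix("cds-")
    raise FormatError(f"CDS feature at {feature.seqid}:{feature.start} carries no gene identifier")


def read_genome(fasta_path: str | Path, gff_path: str | Path) -> list[CDSRecord]:
    """Extract one :class:`CDSRecord` per protein-coding gene from FASTA + GFF3.

    GFF coordinates are 1-based inclusive; minus-strand features are
    reverse-complemented into coding orientation, and the upstream context
    is taken on the coding strand (i.e. 3' of the feature end in genome
    coordinates for minus-strand genes).  Multi-part CDS features sharing a
    gene identifier are concatenated in genomic order before
    strand-resolution (a rare edge in bacterial annotations).

    Pseudogenes are flagged from feature type ``pseudogene`` or a
    ``pseudo=true`` attribute and kept — downstream resampling excludes
    them but the expression pipeline does not.
    """
    contigs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    if not contigs:
        raise FormatError(f"no sequences in {fasta_path}")
    db = gffutils.create_db(
        str(gff_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    parts: dict[str, list] = {}
    for ft in db.all_features():
        if ft.featuretype not in ("CDS", "pseudogene"):
            continue
        parts.setdefault(_feature_gene_id(ft), []).append(ft)

    records: list[CDSRecord] = []
    for gid, fts in parts.items():
        fts = sorted(fts, key=lambda f: f.start)
        seqid = fts[0].seqid
        strand = fts[0].strand
        if seqid not in contigs:
            raise FormatError(f"{gid}: seqid {seqid!r} not present in FASTA")
        contig = contigs[seqid]
        pseudo = any(
            f.featuretype == "pseudogene"
            or f.attributes.get("pseudo", ["false"])[0].lower() == "true"
            for f in fts
        )
        genomic = "".join(contig[f.start - 1 : f.end] for f in fts)
        if strand == "-":
            cds = str(Seq(genomic).reverse_complement())
            up_end = fts[-1].end
            upstream = str(Seq(contig[up_end : up_end + 50]).reverse_complement())
        else:
            cds = genomic
            start = fts[0].start
            upstream = contig[max(0, start - 51) : start - 1]
        if len(upstream) < 50:
            warnings.warn(f"{gid}: upstream context truncated to {len(upstream)} nt (contig edge)")
        records.append(CDSRecord.from_sequence(gid, strand, cds, upstream, pseudo))
    return records


# ---------------------------------------------------------------------------
# Result tables


def write_results_table(records, path: str | Path) -> None:
    """Serialize uniform records to a deterministic TSV.

    Accepts a DataFrame or an iterable of mappings/dataclasses with
    identical fields.  Column order follows the input field order, rows
    with a ``gene_id`` field are sorted by it, floats use the ``.`` decimal
    separator, and identical inputs serialize byte-identically.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        rows = []
        for rec in records:
            if hasattr(rec, "__dataclass_fields__"):
                rows.append({k: getattr(rec, k) for k in rec.__dataclass_fields__})
            elif hasattr(rec, "_asdict"):
                rows.append(rec._asdict())
            else:
                rows.append(dict(rec))
        if rows:
            first = list(rows[0].keys())
            for r in rows:
                if list(r.keys()) != first:
                    raise ValueError("records do not have uniform fields")
            df = pd.DataFrame(rows, columns=first)
        else:
            df = pd.DataFrame()
    if "gene_id" in df.columns:
        df = df.sort_values("gene_id", kind="stable").reset_index(drop=True)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_gene_list(gene_ids: Iterable[str], path: str | Path) -> None:
    """One gene id per line — the shape enrichment web tools ingest."""
    with open(path, "w") as fh:
        for gid in sorted(gene_ids):
            fh.write(f"{gid}\n")


# ---------------------------------------------------------------------------
# GEM serialization (genes x samples TSV with a two-line header)


def write_gem(gem, path: str | Path) -> None:
    """Write a GEM as TSV: row 1 sample ids, row 2 design triple, then values."""
    with open(path, "w") as fh:
        fh.write("gene_id\t" + "\t".join(s.sample_id for s in gem.samples) + "\n")
        fh.write(
            f"#design stage={gem.stage}\t"
            + "\t".join(f"{s.fraction}:{s.temperature_c}:{s.replicate}" for s in gem.samples)
            + "\n"
        )
        for rid, row in zip(gem.row_ids, gem.values):
            fh.write(rid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_gem(path: str | Path):
    from .gem_pipeline import GEM  # local import to avoid a cycle

    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        design = fh.readline().rstrip("\n").split("\t")
    if not design or not design[0].startswith("#design"):
        raise FormatError(f"{path}: missing #design header line")
    stage = design[0].split("stage=", 1)[1] if "stage=" in design[0] else "normalized"
    samples = []
    for sid, triple in zip(header[1:], design[1:]):
        frac, temp, rep = triple.split(":")
        samples.append(ArraySample(sid, frac, int(temp), int(rep)))
    df = pd.read_csv(path, sep="\t", skiprows=[1], index_col=0, float_precision="round_trip")
    return GEM(list(df.index), samples, df.to_numpy(float), stage=stage)
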