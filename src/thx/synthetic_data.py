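"""Ground-truthed synthetic inputs with the statistical structure the analysis assumes.

Two generators share one truth assignment:

* :func:`simulate_genome` writes an annotated synthetic genome whose
  translationally-enhanced (TE) gene set differs from the background in
  exactly the ways the composition battery probes: lower G+C (codon
  choice biased away from G/C-ending codons), shorter proteins, enriched
  E/Q/M/V/K/I residues, shifted start/stop codon shares, and an optional
  G+C-rich block centred near +63 of the CDS.

* :func:`simulate_experiment` emits per-array two-channel probe tables
  for a 5-replicate x 2-temperature x 3-fraction design with spiked
  regulation groups (potentiated, TE-only, discordant, transcription-only,
  TE-down, monosome-shift), realistic per-array offset/scale artifacts,
  per-probe technical noise, control probes and a configurable share of
  negative processed signals.

Everything is deterministic under the configuration seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io_formats import (
    ArraySample,
    CDSRecord,
    ProbeTable,
    write_probe_table,
    write_sample_metadata,
)
from .seqfeatures import FAMILIES

AA_LIST = tuple("ACDEFGHIKLMNPQRSTVWY")

#: background amino-acid composition, loosely that of a G+C-rich
#: actinomycete proteome (alanine/glycine/arginine-heavy)
BACKGROUND_AA_FREQ: dict[str, float] = {
    "A": 0.115, "C": 0.008, "D": 0.058, "E": 0.055, "F": 0.030,
    "G": 0.090, "H": 0.021, "I": 0.033, "K": 0.022, "L": 0.102,
    "M": 0.016, "N": 0.020, "P": 0.060, "Q": 0.030, "R": 0.070,
    "S": 0.050, "T": 0.062, "V": 0.082, "W": 0.014, "Y": 0.021,
}
TE_ENRICHED = ("E", "Q", "M", "V", "K", "I")
TE_DEPLETED = ("A", "H", "L", "P", "W", "Y")

#: start/stop codon shares: background mirrors genome-wide usage in a
#: G+C-rich streptomycete, the TE set the shifted usage of the
#: translationally enhanced genes (ATG and the rare TTG start both up,
#: TAA stop up at the expense of TAG/TGA)
BACKGROUND_START_SHARES = {"ATG": 0.617, "GTG": 0.351, "TTG": 0.003}
TE_START_SHARES = {"ATG": 0.657, "GTG": 0.301, "TTG": 0.041}
BACKGROUND_STOP_SHARES = {"TAA": 0.044, "TAG": 0.174, "TGA": 0.781}
TE_STOP_SHARES = {"TAA": 0.082, "TAG": 0.150, "TGA": 0.767}

GROUP_NAMES = (
    "potentiated",
    "te_up_t_unchanged",
    "te_up_t_down",
    "t_up_only",
    "t_down_only",
    "te_down",
    "mono_shift",
)
TE_UP_GROUPS = ("potentiated", "te_up_t_unchanged", "te_up_t_down")


@dataclass
class SimConfig:
    """Study-scale defaults: 2000 genes, 74 TE-up spikes, five replicates.

    The spiked-group sizes mirror a genome-wide heat-shock screen in
    which 74 translationally enhanced genes split into ~15 potentiated,
    ~40 with unchanged transcription and ~19 transcribed downward, plus
    3 TE-down genes, scaled to a 2000-gene desk genome.
    Effect sizes are log2 units.  ``probes_per_gene`` is scaled down from
    the real platform's ~13 probes/gene.
    """

    n_genes: int = 2000
    n_replicates: int = 5
    probes_per_gene: int = 3
    control_probe_frac: float = 0.05
    neg_signal_frac: float = 0.01
    noise_sd: float = 0.3
    tech_sd: float = 0.1
    array_offset_sd: float = 0.3
    array_scale_sd: float = 0.08
    probe_effect_sd: float = 0.5
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    group_sizes: dict = field(
        default_factory=lambda: {
            "potentiated": 15,
            "te_up_t_unchanged": 40,
            "te_up_t_down": 19,
            "t_up_only": 30,
            "t_down_only": 60,
            "te_down": 3,
            "mono_shift": 15,
        }
    )
    delta_t_up: float = 2.0
    delta_t_down: float = -2.0
    delta_te_up: float = 1.5
    delta_te_down: float = -1.5
    mono_shift_effect: float = 1.5
    background_gc: float = 0.72
    te_set_gc: float = 0.62
    median_protein_len: int = 250
    len_sigma: float = 0.45
    te_len_factor: float = 0.6
    gc_block: bool = True
    pseudogene_frac: float = 0.05
    intergenic_len: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.group_sizes) - set(GROUP_NAMES)
        if unknown:
            raise ValueError(f"unknown spike groups: {sorted(unknown)}")
        if sum(self.group_sizes.values()) > self.n_genes:
            raise ValueError("spiked group sizes exceed n_genes")
        if self.n_replicates < 2:
            raise ValueError("need at least two replicates for rank products")

    @property
    def n_te_up(self) -> int:
        return sum(self.group_sizes.get(g, 0) for g in TE_UP_GROUPS)

    def _seeds(self) -> list[np.random.SeedSequence]:
        return np.random.SeedSequence(self.seed).spawn(3)


def plan_truth(cfg: SimConfig) -> pd.DataFrame:
    """Assign spike groups, effects and pseudogene flags to gene ids."""
    rng = np.random.default_rng(cfg._seeds()[0])
    n = cfg.n_genes
    ids = [f"gene{i + 1:05d}" for i in range(n)]
    truth = pd.DataFrame(
        {
            "gene_id": ids,
            "class_label": "null",
            "delta_t": 0.0,
            "delta_te": 0.0,
            "delta_mono": 0.0,
        }
    ).set_index("gene_id", drop=False)

    order = list(GROUP_NAMES)
    total = sum(cfg.group_sizes.get(g, 0) for g in order)
    chosen = rng.choice(n, size=total, replace=False)
    pos = 0
    for group in order:
        size = cfg.group_sizes.get(group, 0)
        sel = chosen[pos : pos + size]
        pos += size
        truth.iloc[sel, truth.columns.get_loc("class_label")] = group
        if group == "potentiated":
            truth.iloc[sel, truth.columns.get_loc("delta_t")] = cfg.delta_t_up
            truth.iloc[sel, truth.columns.get_loc("delta_te")] = cfg.delta_te_up
        elif group == "te_up_t_unchanged":
            truth.iloc[sel, truth.columns.get_loc("delta_te")] = cfg.delta_te_up
        elif group == "te_up_t_down":
            truth.iloc[sel, truth.columns.get_loc("delta_t")] = cfg.delta_t_down
            truth.iloc[sel, truth.columns.get_loc("delta_te")] = cfg.delta_te_up
        elif group == "t_up_only":
            truth.iloc[sel, truth.columns.get_loc("delta_t")] = cfg.delta_t_up
        elif group == "t_down_only":
            truth.iloc[sel, truth.columns.get_loc("delta_t")] = cfg.delta_t_down
        elif group == "te_down":
            truth.iloc[sel, truth.columns.get_loc("delta_te")] = cfg.delta_te_down
        elif group == "mono_shift":
            truth.iloc[sel, truth.columns.get_loc("delta_mono")] = cfg.mono_shift_effect

    truth["in_te_set"] = truth["class_label"].isin(TE_UP_GROUPS)
    null_idx = np.flatnonzero((truth["class_label"] == "null").to_numpy())
    n_pseudo = int(round(cfg.pseudogene_frac * n))
    pseudo = rng.choice(null_idx, size=min(n_pseudo, null_idx.size), replace=False)
    is_pseudo = np.zeros(n, dtype=bool)
    is_pseudo[pseudo] = True
    truth["is_pseudogene"] = is_pseudo
    return truth


# ---------------------------------------------------------------------------
# Genome generation


def _codon_weights(theta: float) -> dict[str, np.ndarray]:
    out = {}
    for aa, fam in FAMILIES.items():
        gc = np.array([c.count("G") + c.count("C") for c in fam], dtype=float)
        w = theta**gc
        out[aa] = w / w.sum()
    return out


def _expected_gc(theta: float, aa_freq: Mapping[str, float]) -> float:
    probs = _codon_weights(theta)
    total = 0.0
    for aa, f in aa_freq.items():
        gc = np.array([c.count("G") + c.count("C") for c in FAMILIES[aa]], dtype=float)
        total += f * float(probs[aa] @ gc)
    return total / 3.0


def _calibrate_theta(aa_freq: Mapping[str, float], target_gc: float) -> float:
    """Solve for the codon G+C bias that realizes ``target_gc`` under ``aa_freq``."""
    lo, hi = np.exp(-8), np.exp(8)
    gc_lo, gc_hi = _expected_gc(lo, aa_freq), _expected_gc(hi, aa_freq)
    if not gc_lo <= target_gc <= gc_hi:
        raise ValueError(
            f"contradictory composition targets: GC {target_gc:.3f} outside the "
            f"achievable range [{gc_lo:.3f}, {gc_hi:.3f}] for this amino-acid composition"
        )
    return float(brentq(lambda t: _expected_gc(t, aa_freq) - target_gc, lo, hi, xtol=1e-6))


def _te_aa_freq() -> dict[str, float]:
    freq = dict(BACKGROUND_AA_FREQ)
    for aa in TE_ENRICHED:
        freq[aa] *= 1.6
    for aa in TE_DEPLETED:
        freq[aa] *= 0.65
    total = sum(freq.values())
    return {aa: f / total for aa, f in freq.items()}


def _normalized(shares: Mapping[str, float]) -> tuple[list[str], np.ndarray]:
    keys = list(shares)
    vals = np.array([shares[k] for k in keys], dtype=float)
    return keys, vals / vals.sum()


_MAX_GC_CODON = {
    aa: max(fam, key=lambda c: (c.count("G") + c.count("C"), c)) for aa, fam in FAMILIES.items()
}


def _random_dna(rng: np.random.Generator, length: int, gc: float) -> str:
    bases = rng.choice(
        np.array(list("GCAT")), size=length, p=[gc / 2, gc / 2, (1 - gc) / 2, (1 - gc) / 2]
    )
    return "".join(bases)


def _build_cds(
    rng: np.random.Generator,
    n_res: int,
    aa_freq: Mapping[str, float],
    codon_probs: Mapping[str, np.ndarray],
    start_codon: str,
    stop_codon: str,
    gc_block: bool,
) -> str:
    aas = rng.choice(np.array(AA_LIST), size=n_res, p=np.array([aa_freq[a] for a in AA_LIST]))
    codons = np.empty(n_res, dtype=object)
    for aa in set(aas.tolist()):
        fam = FAMILIES[aa]
        where = np.flatnonzero(aas == aa)
        picks = rng.choice(len(fam), size=where.size, p=codon_probs[aa])
        codons[where] = np.array(fam, dtype=object)[picks]
    if gc_block:
        # codons 18..23 after the start codon cover nt +55..+72: a
        # G+C-rich island centred near +63 of the CDS
        for i in range(17, min(23, n_res)):
            codons[i] = _MAX_GC_CODON[aas[i]]
    return start_codon + "".join(codons.tolist()) + stop_codon


@dataclass
class SyntheticGenome:
    """A single synthetic contig with its annotation and per-gene truth."""

    contig_id: str
    sequence: str
    features: pd.DataFrame  # gene_id, start, end, strand, is_pseudogene (1-based inclusive)
    truth: pd.DataFrame
    upstream50: dict[str, str]
    cds: dict[str, str]

    def to_cds_records(self) -> list[CDSRecord]:
        import warnings as _w

        records = []
        with _w.catch_warnings():
            _w.simplefilter("ignore")  # synthetic pseudogenes may carry odd codons
            for f in self.features.itertuples():
                records.append(
                    CDSRecord.from_sequence(
                        f.gene_id,
                        f.strand,
                        self.cds[f.gene_id],
                        self.upstream50[f.gene_id],
                        bool(f.is_pseudogene),
                    )
                )
        return records

    def orf_lengths(self) -> dict[str, int]:
        return {g: len(s) for g, s in self.cds.items()}

    def write(self, fasta_path: str | Path, gff_path: str | Path) -> None:
        with open(fasta_path, "w") as fh:
            fh.write(f">{self.contig_id}\n")
            for i in range(0, len(self.sequence), 70):
                fh.write(self.sequence[i : i + 70] + "\n")
        with open(gff_path, "w") as fh:
            fh.write("##gff-version 3\n")
            fh.write(f"##sequence-region {self.contig_id} 1 {len(self.sequence)}\n")
            for f in self.features.itertuples():
                attrs = f"ID=cds-{f.gene_id};locus_tag={f.gene_id}"
                if f.is_pseudogene:
                    attrs += ";pseudo=true"
                fh.write(
                    f"{self.contig_id}\tthx_sim\tCDS\t{f.start}\t{f.end}\t.\t{f.strand}\t0\t{attrs}\n"
                )


def simulate_genome(cfg: SimConfig, truth: pd.DataFrame | None = None) -> SyntheticGenome:
    """Generate FASTA/GFF-ready genome with composition-shifted TE genes.

    Genes are drawn codon by codon: residues from a background or
    TE-shifted amino-acid distribution, codons within each synonymous
    family with a G+C bias calibrated so the realized CDS G+C matches
    ``background_gc`` (``te_set_gc`` for the TE set).  Monosome-shift
    genes are built short (< 1000 nt ORF) to carry the partitioning
    associations.  Intergenic spacers are ``intergenic_len`` bp; the 50 bp
    immediately upstream of each TE gene are drawn at the TE G+C level.
    """
    if truth is None:
        truth = plan_truth(cfg)
    rng = np.random.default_rng(cfg._seeds()[1])

    bg_freq = {aa: f / sum(BACKGROUND_AA_FREQ.values()) for aa, f in BACKGROUND_AA_FREQ.items()}
    te_freq = _te_aa_freq()
    theta_bg = _calibrate_theta(bg_freq, cfg.background_gc)
    theta_te = _calibrate_theta(te_freq, cfg.te_set_gc)
    probs_bg = _codon_weights(theta_bg)
    probs_te = _codon_weights(theta_te)
    start_bg, p_start_bg = _normalized(BACKGROUND_START_SHARES)
    start_te, p_start_te = _normalized(TE_START_SHARES)
    stop_bg, p_stop_bg = _normalized(BACKGROUND_STOP_SHARES)
    stop_te, p_stop_te = _normalized(TE_STOP_SHARES)

    pieces: list[str] = []
    cursor = 0
    rows = []
    upstream50: dict[str, str] = {}
    cds_map: dict[str, str] = {}
    te_mask = truth["in_te_set"].to_numpy()
    mono_mask = (truth["class_label"] == "mono_shift").to_numpy()

    for i, gid in enumerate(truth["gene_id"]):
        is_te = bool(te_mask[i])
        if mono_mask[i]:
            n_res = int(np.clip(rng.lognormal(np.log(120), 0.3), 50, 320))
        else:
            median = cfg.median_protein_len * (cfg.te_len_factor if is_te else 1.0)
            n_res = int(np.clip(rng.lognormal(np.log(median), cfg.len_sigma), 50, 3000))
        if is_te:
            start = str(rng.choice(start_te, p=p_start_te))
            stop = str(rng.choice(stop_te, p=p_stop_te))
            cds = _build_cds(rng, n_res, te_freq, probs_te, start, stop, cfg.gc_block)
            spacer_gc, near_gc = cfg.background_gc, cfg.te_set_gc
        else:
            start = str(rng.choice(start_bg, p=p_start_bg))
            stop = str(rng.choice(stop_bg, p=p_stop_bg))
            cds = _build_cds(rng, n_res, bg_freq, probs_bg, start, stop, False)
            spacer_gc = near_gc = cfg.background_gc
        spacer = _random_dna(rng, max(cfg.intergenic_len - 50, 0), spacer_gc) + _random_dna(
            rng, min(50, cfg.intergenic_len), near_gc
        )
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            pieces.append(spacer)
            cursor += len(spacer)
            start_pos = cursor + 1
            pieces.append(cds)
            cursor += len(cds)
            rows.append((gid, start_pos, cursor, "+"))
        else:
            from Bio.Seq import Seq

            segment = str(Seq(spacer + cds).reverse_complement())
            start_pos = cursor + 1
            pieces.append(segment)
            rows.append((gid, start_pos, start_pos + len(cds) - 1, "-"))
            cursor += len(segment)
        upstream50[gid] = spacer[-50:]
        cds_map[gid] = cds
    pieces.append(_random_dna(rng, cfg.intergenic_len, cfg.background_gc))

    features = pd.DataFrame(rows, columns=["gene_id", "start", "end", "strand"])
    features["is_pseudogene"] = truth["is_pseudogene"].to_numpy()
    genome = SyntheticGenome(
        "synchr1", "".join(pieces), features, truth, upstream50, cds_map
    )
    truth["orf_len_nt"] = [len(cds_map[g]) for g in truth["gene_id"]]
    truth["start_codon"] = [cds_map[g][:3] for g in truth["gene_id"]]
    return genome


# ---------------------------------------------------------------------------
# Experiment generation


def _negate_low_tail(rng: np.random.Generator, values: np.ndarray, frac: float) -> None:
    """Negate ~``frac`` of entries, drawn from the channel's weakest tail.

    Background subtraction produces negative processed signals where the
    raw intensity is near background, so negatives live at the very
    bottom of the intensity distribution — negating strong features would
    model an artifact the platform does not produce.  Candidates are the
    lowest ``3 * frac`` share of the channel, each negated with
    probability 1/3, so the expected negation count is
    ``frac * len(values)``.  In-place.
    """
    if frac <= 0:
        return
    n = values.size
    k = max(1, int(np.ceil(min(0.10, 3.0 * frac) * n)))
    candidates = np.argsort(values)[:k]
    p = min(1.0, frac * n / k)
    hit = candidates[rng.random(k) < p]
    values[hit] *= -1


@dataclass
class SyntheticExperiment:
    tables: list[ProbeTable]
    samples: list[ArraySample]
    truth: pd.DataFrame


def simulate_experiment(cfg: SimConfig, truth: pd.DataFrame | None = None) -> SyntheticExperiment:
    """Two-channel probe tables for the full fraction x temperature design.

    Expression model (log2): per-gene baseline ~ N(8, 1) (monosome-shift
    genes drawn low, N(6.5, 0.5), so their low-abundance association is
    real); heat adds the true transcriptional effect; ribosomal fractions
    add a gene-specific fraction offset plus the true TE effect at 42 °C;
    the monosome additionally receives the mono-shift effect.  Biological
    noise is per gene/fraction/temperature/replicate; arrays carry an
    offset and a mild scale artifact (what centering and scale
    normalization exist to remove); probes carry an affinity effect shared
    across arrays plus technical noise.  Channel intensities follow
    reference = 2^(10 + probe effect + noise), signal = reference x
    2^(array-distorted gene log-ratio); a ``neg_signal_frac`` share of
    entries in each channel is negated to exercise the negative-value
    rules, and control probes are appended.
    """
    if truth is None:
        truth = plan_truth(cfg)
    rng = np.random.default_rng(cfg._seeds()[2])
    n = cfg.n_genes
    ppg = cfg.probes_per_gene

    mono_mask = (truth["class_label"] == "mono_shift").to_numpy()
    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=n)
    baseline[mono_mask] = rng.normal(6.5, 0.5, size=int(mono_mask.sum()))
    te_base = rng.normal(0.0, 0.5, size=n)
    mono_base = rng.normal(-0.5, 0.5, size=n)
    d_t = truth["delta_t"].to_numpy()
    d_te = truth["delta_te"].to_numpy()
    d_mono = truth["delta_mono"].to_numpy()

    samples = [
        ArraySample(f"{frac}{temp}r{rep}", frac, temp, rep)
        for frac in ("total", "monosome", "polysome")
        for temp in (30, 42)
        for rep in range(1, cfg.n_replicates + 1)
    ]
    n_arrays = len(samples)

    # ribosomal fractions are built on the *realized* total-RNA value of the
    # same culture: they are aliquots of one lysate, so culture-level
    # abundance fluctuations propagate into (and cancel out of) TE
    x_by_key: dict[tuple[str, int, int], np.ndarray] = {}
    for temp in (30, 42):
        hot = 1.0 if temp == 42 else 0.0
        for rep in range(1, cfg.n_replicates + 1):
            tot = baseline + d_t * hot + rng.normal(0.0, cfg.noise_sd, size=n)
            poly = tot + te_base + d_te * hot + rng.normal(0.0, cfg.noise_sd, size=n)
            mono = (
                tot + mono_base + d_te * hot + d_mono * hot
                + rng.normal(0.0, cfg.noise_sd, size=n)
            )
            x_by_key[("total", temp, rep)] = tot
            x_by_key[("polysome", temp, rep)] = poly
            x_by_key[("monosome", temp, rep)] = mono
    x = np.column_stack([x_by_key[s.design_key] for s in samples])

    probe_ids = [f"{g}_p{k + 1}" for g in truth["gene_id"] for k in range(ppg)]
    gene_of_probe = np.repeat(np.arange(n), ppg)
    n_probes = len(probe_ids)
    probe_effect = rng.normal(0.0, cfg.probe_effect_sd, size=n_probes)
    array_offset = rng.normal(0.0, cfg.array_offset_sd, size=n_arrays)
    array_scale = np.exp(rng.normal(0.0, cfg.array_scale_sd, size=n_arrays))

    n_ctrl = int(round(cfg.control_probe_frac * n_probes))
    ctrl_ids = [f"CTRL_{k + 1:05d}" for k in range(n_ctrl)]

    tables = []
    for j, s in enumerate(samples):
        tech = rng.normal(0.0, cfg.tech_sd, size=n_probes)
        ref_log2 = 10.0 + probe_effect + rng.normal(0.0, cfg.tech_sd, size=n_probes)
        lr = array_scale[j] * (x[gene_of_probe, j] + tech) + array_offset[j]
        sig_log2 = ref_log2 + lr
        signal = 2.0**sig_log2
        reference = 2.0**ref_log2
        ctrl_ref = 2.0 ** (10.0 + rng.normal(0.0, 1.0, size=n_ctrl))
        ctrl_sig = ctrl_ref * 2.0 ** rng.normal(0.0, 1.0, size=n_ctrl)
        signal = np.concatenate([signal, ctrl_sig])
        reference = np.concatenate([reference, ctrl_ref])
        _negate_low_tail(rng, signal, cfg.neg_signal_frac)
        _negate_low_tail(rng, reference, cfg.neg_signal_frac)
        df = pd.DataFrame(
            {
                "probe_id": probe_ids + ctrl_ids,
                "gene_id": [truth["gene_id"].iloc[g] for g in gene_of_probe] + [""] * n_ctrl,
                "is_control": [False] * n_probes + [True] * n_ctrl,
                "signal": signal,
                "reference": reference,
            }
        )
        tables.append(ProbeTable(df, s))
    return SyntheticExperiment(tables, samples, truth)


@dataclass
class SimResult:
    genome: SyntheticGenome
    experiment: SyntheticExperiment
    truth: pd.DataFrame


def simulate(cfg: SimConfig) -> SimResult:
    """Genome and experiment from one shared truth assignment."""
    truth = plan_truth(cfg)
    genome = simulate_genome(cfg, truth)
    experiment = simulate_experiment(cfg, truth)
    return SimResult(genome, experiment, truth)


def write_simulation(sim: SimResult, outdir: str | Path) -> None:
    """Emit probes/*.tsv, meta.tsv, probemap.tsv, genome.fa, genome.gff3, truth.tsv."""
    outdir = Path(outdir)
    (outdir / "probes").mkdir(parents=True, exist_ok=True)
    for table in sim.experiment.tables:
        write_probe_table(table, outdir / "probes" / f"{table.sample.sample_id}.tsv")
    write_sample_metadata(sim.experiment.samples, outdir / "meta.tsv")
    first = sim.experiment.tables[0].data
    probemap = first.loc[~first["is_control"], ["probe_id", "gene_id"]]
    probemap.to_csv(outdir / "probemap.tsv", sep="\t", index=False, lineterminator="\n")
    sim.genome.write(outdir / "genome.fa", outdir / "genome.gff3")
    sim.truth.reset_index(drop=True).to_csv(
        outdir / "truth.tsv", sep="\t", index=False, lineterminator="\n"
    )
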