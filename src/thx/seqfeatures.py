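"""Sequence-composition characterization of a gene set against the genome.

A significant gene set (for example, the translationally enhanced genes)
is compared to the genome on protein length, amino-acid composition, G+C
content in three windows (50 bp upstream of the start codon, first 50
coding bp, full CDS), a positional G+C profile around the start codon,
relative synonymous codon usage (RSCU), and start/stop codon choice.

Each set-level statistic is judged against a resampling null: 1000 random
gene sets of the same size, drawn uniformly without replacement from all
protein-coding genes excluding pseudogenes.  A statistic more than 2
standard deviations above or below the null mean is flagged significant.
Classical one-tailed tests (Wilcoxon rank-sum for lengths, Welch t for
G+C) against the all-gene distributions are reported alongside.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from scipy.stats import mannwhitneyu, ttest_ind, wilcoxon

from .io_formats import CDSRecord, START_CODONS, STOP_CODONS

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"

_standard = CodonTable.unambiguous_dna_by_id[1]
SENSE_CODONS: tuple[str, ...] = tuple(sorted(_standard.forward_table))
FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon, _aa in _standard.forward_table.items():
    FAMILIES.setdefault(_aa, ())
FAMILIES = {
    aa: tuple(sorted(c for c, a in _standard.forward_table.items() if a == aa))
    for aa in FAMILIES
}
#: the 59 codons entering RSCU: synonymous families of size >= 2 only
#: (ATG and TGG carry no synonymous choice; stop codons are tabulated
#: separately by :func:`start_stop_usage`)
RSCU_CODONS: tuple[str, ...] = tuple(
    sorted(c for aa, fam in FAMILIES.items() if len(fam) >= 2 for c in fam)
)
_RSCU_INDEX = {c: i for i, c in enumerate(RSCU_CODONS)}
_FAMILY_COLS: dict[str, np.ndarray] = {
    aa: np.array([_RSCU_INDEX[c] for c in fam])
    for aa, fam in FAMILIES.items()
    if len(fam) >= 2
}


def _gc_count(seq: str) -> int:
    return seq.count("G") + seq.count("C")


@dataclass
class GenomeProfile:
    """Precomputed per-gene composition features for fast resampling.

    Pseudogenes and out-of-frame records are kept (indexed) but excluded
    from the eligible pool used for random-set draws and background
    distributions.
    """

    gene_ids: list[str]
    eligible: np.ndarray
    protein_len: np.ndarray
    aa_counts: np.ndarray  # n x 20
    codon_counts: np.ndarray  # n x 59, internal codons only
    start_codon: list[str]
    stop_codon: list[str]
    up_gc: np.ndarray
    up_len: np.ndarray
    down_gc: np.ndarray
    down_len: np.ndarray
    cds_gc: np.ndarray
    cds_len: np.ndarray
    seqs: list[tuple[str, str]]  # (upstream50, cds)
    _id_index: dict[str, int] = field(default_factory=dict, repr=False)

    @classmethod
    def from_records(cls, records: Sequence[CDSRecord]) -> "GenomeProfile":
        n = len(records)
        aa_counts = np.zeros((n, 20), dtype=np.int64)
        codon_counts = np.zeros((n, len(RSCU_CODONS)), dtype=np.int64)
        protein_len = np.zeros(n, dtype=np.int64)
        up_gc = np.zeros(n, dtype=np.int64)
        up_len = np.zeros(n, dtype=np.int64)
        down_gc = np.zeros(n, dtype=np.int64)
        down_len = np.zeros(n, dtype=np.int64)
        cds_gc = np.zeros(n, dtype=np.int64)
        cds_len = np.zeros(n, dtype=np.int64)
        eligible = np.zeros(n, dtype=bool)
        starts, stops, seqs, ids = [], [], [], []
        aa_index = {a: i for i, a in enumerate(AA_ORDER)}
        for i, rec in enumerate(records):
            ids.append(rec.gene_id)
            eligible[i] = not rec.is_pseudogene and rec.frame_ok
            protein_len[i] = len(rec.protein)
            for aa, cnt in Counter(rec.protein).items():
                if aa in aa_index:
                    aa_counts[i, aa_index[aa]] = cnt
            if rec.frame_ok and len(rec.cds) >= 9:
                # internal codons: start and stop excluded — their identity
                # is constrained and tabulated separately
                internal = rec.cds[3 : len(rec.cds) - 3]
                for j in range(0, len(internal), 3):
                    idx = _RSCU_INDEX.get(internal[j : j + 3])
                    if idx is not None:
                        codon_counts[i, idx] += 1
            starts.append(rec.cds[:3] if len(rec.cds) >= 3 else "")
            stops.append(rec.stop_codon)
            up_gc[i] = _gc_count(rec.upstream50)
            up_len[i] = len(rec.upstream50)
            down = rec.cds[:50]
            down_gc[i] = _gc_count(down)
            down_len[i] = len(down)
            cds_gc[i] = _gc_count(rec.cds)
            cds_len[i] = len(rec.cds)
            seqs.append((rec.upstream50, rec.cds))
        return cls(
            ids, eligible, protein_len, aa_counts, codon_counts, starts, stops,
            up_gc, up_len, down_gc, down_len, cds_gc, cds_len, seqs,
            {g: i for i, g in enumerate(ids)},
        )

    def indices(self, gene_ids: Iterable[str]) -> np.ndarray:
        try:
            return np.array([self._id_index[g] for g in gene_ids], dtype=np.int64)
        except KeyError as exc:
            raise KeyError(f"gene {exc.args[0]!r} not in genome") from None

    @property
    def n_eligible(self) -> int:
        return int(self.eligible.sum())


@dataclass(frozen=True)
class NullComparison:
    """One observed set statistic against its resampled null distribution."""

    statistic_name: str
    observed: float
    null_mean: float
    null_sd: float
    z: float
    significant: bool
    direction: str  # higher | lower | none
    n_sets: int
    seed: int

    @classmethod
    def from_null(
        cls, name: str, observed: float, null_values: np.ndarray, seed: int
    ) -> "NullComparison":
        null_values = np.asarray(null_values, dtype=float)
        mean = float(np.nanmean(null_values))
        sd = float(np.nanstd(null_values, ddof=1))
        if sd <= 0:
            raise ValueError(f"{name}: degenerate null (sd = 0)")
        z = (float(observed) - mean) / sd
        direction = "higher" if z > 2 else ("lower" if z < -2 else "none")
        return cls(name, float(observed), mean, sd, z, abs(z) > 2, direction,
                   len(null_values), seed)


def sample_random_sets(
    profile: GenomeProfile | Sequence[CDSRecord],
    set_size: int,
    n_sets: int = 1000,
    seed: int = 0,
) -> list[list[str]]:
    """Uniform without-replacement gene-id sets from the eligible pool."""
    if not isinstance(profile, GenomeProfile):
        profile = GenomeProfile.from_records(profile)
    rng = np.random.default_rng(seed)
    idx = _random_index_sets(profile, set_size, n_sets, rng)
    return [[profile.gene_ids[i] for i in row] for row in idx]


def _random_index_sets(
    profile: GenomeProfile, set_size: int, n_sets: int, rng: np.random.Generator
) -> np.ndarray:
    pool = np.flatnonzero(profile.eligible)
    if set_size > pool.size:
        raise ValueError(f"set_size {set_size} exceeds {pool.size} eligible genes")
    return np.stack([rng.choice(pool, size=set_size, replace=False) for _ in range(n_sets)])


# ---------------------------------------------------------------------------
# Individual analyses


@dataclass
class LengthStats:
    comparison: NullComparison
    wilcoxon_p: float
    set_median: float
    genome_median: float


def protein_length_stats(
    sig_set: Iterable[str],
    profile: GenomeProfile,
    n_sets: int = 1000,
    seed: int = 0,
    null_idx: np.ndarray | None = None,
) -> LengthStats:
    """Are the set's proteins shorter than expected?

    (i) one-tailed Wilcoxon rank-sum of set protein lengths against all
    eligible genes (alternative: shorter); (ii) total residue count of
    the set against the null distribution of total residues over random
    same-size sets.
    """
    idx = profile.indices(sig_set)
    if idx.size == 0:
        raise ValueError("empty gene set")
    rng = np.random.default_rng(seed)
    if null_idx is None:
        null_idx = _random_index_sets(profile, idx.size, n_sets, rng)
    lengths = profile.protein_len
    sig = lengths[idx]
    background = lengths[profile.eligible]
    p = float(mannwhitneyu(sig, background, alternative="less").pvalue)
    null_totals = lengths[null_idx].sum(axis=1)
    comp = NullComparison.from_null("total_protein_residues", float(sig.sum()), null_totals, seed)
    return LengthStats(comp, p, float(np.median(sig)), float(np.median(background)))


def aa_frequency(gene_set: Iterable[str], profile: GenomeProfile) -> pd.Series:
    """Pooled amino-acid frequency per 100 residues; sums to 100."""
    idx = profile.indices(gene_set)
    counts = profile.aa_counts[idx].sum(axis=0)
    total = counts.sum()
    if total == 0:
        raise ValueError("gene set encodes no residues")
    return pd.Series(100.0 * counts / total, index=list(AA_ORDER), name="freq_per_100")


def compare_aa_frequencies(
    sig_set: Iterable[str],
    profile: GenomeProfile,
    n_sets: int = 1000,
    seed: int = 0,
    null_idx: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-residue pooled frequencies against the random-set null.

    Returns one row per amino acid (observed, null_mean, null_sd, z,
    significant, direction).  ``attrs['wilcoxon_p']`` carries a paired
    signed-rank p-value over the 20 residues (observed vs null mean), a
    set-level companion to the per-residue flags.
    """
    idx = profile.indices(sig_set)
    rng = np.random.default_rng(seed)
    if null_idx is None:
        null_idx = _random_index_sets(profile, idx.size, n_sets, rng)
    obs = aa_frequency(sig_set, profile).to_numpy()
    counts = profile.aa_counts[null_idx].sum(axis=1)  # n_sets x 20
    freqs = 100.0 * counts / counts.sum(axis=1, keepdims=True)
    df = _vector_comparison(obs, freqs, list(AA_ORDER))
    diffs = obs - df["null_mean"].to_numpy()
    df.attrs["wilcoxon_p"] = 1.0 if np.allclose(diffs, 0) else float(wilcoxon(diffs).pvalue)
    df.attrs["n_sets"] = int(null_idx.shape[0])
    df.attrs["seed"] = seed
    return df


def _vector_comparison(obs: np.ndarray, null: np.ndarray, index: list[str]) -> pd.DataFrame:
    mean = np.nanmean(null, axis=0)
    sd = np.nanstd(null, axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (obs - mean) / sd
    z = np.where(sd > 0, z, np.nan)
    if (sd == 0).any():
        warnings.warn(f"{int((sd == 0).sum())} statistics have a degenerate null (sd = 0)")
    direction = np.where(z > 2, "higher", np.where(z < -2, "lower", "none"))
    return pd.DataFrame(
        {
            "observed": obs,
            "null_mean": mean,
            "null_sd": sd,
            "z": z,
            "significant": np.abs(z) > 2,
            "direction": direction,
        },
        index=index,
    )


GC_WINDOWS = ("upstream50_gc", "downstream50_gc", "full_cds_gc")


def gc_windows(gene_set: Iterable[str], profile: GenomeProfile) -> pd.DataFrame:
    """Per-gene G+C percentage of the three windows (values in [0, 100]).

    Genes with truncated upstream context get NaN in ``upstream50_gc``.
    """
    idx = profile.indices(gene_set)
    with np.errstate(invalid="ignore", divide="ignore"):
        up = np.where(
            profile.up_len[idx] == 50, 100.0 * profile.up_gc[idx] / profile.up_len[idx], np.nan
        )
        down = 100.0 * profile.down_gc[idx] / profile.down_len[idx]
        full = 100.0 * profile.cds_gc[idx] / profile.cds_len[idx]
    return pd.DataFrame(
        {"upstream50_gc": up, "downstream50_gc": down, "full_cds_gc": full},
        index=[profile.gene_ids[i] for i in idx],
    )


def compare_gc_windows(
    sig_set: Iterable[str],
    profile: GenomeProfile,
    n_sets: int = 1000,
    seed: int = 0,
    null_idx: np.ndarray | None = None,
) -> pd.DataFrame:
    """Window G+C of the set vs random sets and vs all genes.

    One row per window with the resampling z (set mean of per-gene GC%)
    and a one-tailed Welch t-test p-value (alternative: set lower)
    against the all-gene per-gene values.
    """
    idx = profile.indices(sig_set)
    rng = np.random.default_rng(seed)
    if null_idx is None:
        null_idx = _random_index_sets(profile, idx.size, n_sets, rng)
    per_gene = _per_gene_gc(profile)
    n_trunc = int(np.isnan(per_gene[:, 0])[idx].sum())
    if n_trunc:
        warnings.warn(f"{n_trunc} genes with truncated upstream dropped from the upstream window")
    obs = np.nanmean(per_gene[idx], axis=0)
    null_means = np.nanmean(per_gene[null_idx], axis=1)  # n_sets x 3
    df = _vector_comparison(obs, null_means, list(GC_WINDOWS))
    background = per_gene[profile.eligible]
    pvals = []
    for w in range(3):
        a = per_gene[idx, w]
        b = background[:, w]
        pvals.append(
            float(
                ttest_ind(
                    a[~np.isnan(a)], b[~np.isnan(b)], equal_var=False, alternative="less"
                ).pvalue
            )
        )
    df["t_p_lower"] = pvals
    df.attrs["n_sets"] = int(null_idx.shape[0])
    df.attrs["seed"] = seed
    return df


def _per_gene_gc(profile: GenomeProfile) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        up = np.where(profile.up_len == 50, 100.0 * profile.up_gc / profile.up_len, np.nan)
        down = np.where(profile.down_len > 0, 100.0 * profile.down_gc / profile.down_len, np.nan)
        full = np.where(profile.cds_len > 0, 100.0 * profile.cds_gc / profile.cds_len, np.nan)
    return np.column_stack([up, down, full])


def gc_positional_profile(
    gene_set: Iterable[str],
    profile: GenomeProfile,
    half_window: int = 12,
    start: int = -50,
    end: int = 300,
) -> pd.Series:
    """Mean windowed G+C fraction per position relative to the start codon.

    Position +1 is the first base of the start codon, -1 the last upstream
    base; there is no position 0.  At each position the G+C fraction of
    the +-``half_window`` nt window is averaged over the genes whose
    sequence fully covers that window; genes lacking coverage are excluded
    at that position.  Values are percentages.
    """
    idx = profile.indices(gene_set)
    positions = [p for p in range(start, end + 1) if p != 0]
    n_pos = len(positions)
    upstream_span = sum(1 for p in positions if p < 0)
    width = 2 * half_window + 1
    mat = np.full((len(idx), n_pos), np.nan)
    for row, i in enumerate(idx):
        up, cds = profile.seqs[i]
        gc = np.full(n_pos, np.nan)
        for col, p in enumerate(positions):
            if p < 0:
                k = len(up) + p  # p = -1 -> last upstream base
                if k >= 0:
                    gc[col] = up[k] in "GC"
            else:
                k = p - 1
                if k < len(cds):
                    gc[col] = cds[k] in "GC"
        padded = np.concatenate([np.full(half_window, np.nan), gc, np.full(half_window, np.nan)])
        windows = np.lib.stride_tricks.sliding_window_view(padded, width)
        mat[row] = np.where(np.isnan(windows).any(axis=1), np.nan, np.nansum(windows, axis=1) / width)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns at the edges
        out = 100.0 * np.nanmean(mat, axis=0)
    return pd.Series(out, index=positions, name="gc_percent")


def rscu(gene_set: Iterable[str], profile: GenomeProfile) -> pd.Series:
    """Pooled relative synonymous codon usage over the 59 multi-codon-family codons.

    RSCU(c) = count(c) / mean count over c's synonymous family.  Family
    means are exactly 1 whenever the family is observed at all; unobserved
    families yield NaN.  Start codons are excluded from the counts (their
    identity is constrained) and stop codons are handled separately.
    """
    idx = profile.indices(gene_set)
    counts = profile.codon_counts[idx].sum(axis=0).astype(float)
    out = np.full(len(RSCU_CODONS), np.nan)
    for aa, cols in _FAMILY_COLS.items():
        fam_total = counts[cols].sum()
        if fam_total > 0:
            out[cols] = counts[cols] / (fam_total / len(cols))
    return pd.Series(out, index=list(RSCU_CODONS), name="rscu")


def compare_rscu(
    sig_set: Iterable[str],
    profile: GenomeProfile,
    n_sets: int = 1000,
    seed: int = 0,
    null_idx: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-codon RSCU of the set against the random-set null."""
    idx = profile.indices(sig_set)
    rng = np.random.default_rng(seed)
    if null_idx is None:
        null_idx = _random_index_sets(profile, idx.size, n_sets, rng)
    obs = rscu(sig_set, profile).to_numpy()
    counts = profile.codon_counts[null_idx].sum(axis=1).astype(float)  # n_sets x 59
    null = np.full_like(counts, np.nan)
    for aa, cols in _FAMILY_COLS.items():
        fam_totals = counts[:, cols].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            null[:, cols] = counts[:, cols] / (fam_totals[:, None] / len(cols))
    df = _vector_comparison(obs, null, list(RSCU_CODONS))
    df.attrs["n_sets"] = int(null_idx.shape[0])
    df.attrs["seed"] = seed
    return df


def start_stop_usage(gene_set: Iterable[str], profile: GenomeProfile) -> tuple[pd.Series, pd.Series]:
    """Percentage start- and stop-codon usage of the set (each sums to 100)."""
    idx = profile.indices(gene_set)
    if idx.size == 0:
        raise ValueError("empty gene set")
    starts = pd.Series(0.0, index=list(START_CODONS) + ["other"])
    stops = pd.Series(0.0, index=list(STOP_CODONS) + ["other"])
    for i in idx:
        s = profile.start_codon[i]
        starts[s if s in START_CODONS else "other"] += 1
        e = profile.stop_codon[i]
        stops[e if e in STOP_CODONS else "other"] += 1
    return 100.0 * starts / idx.size, 100.0 * stops / idx.size


# ---------------------------------------------------------------------------
# The full battery


@dataclass
class CompositionBattery:
    """All composition analyses of one gene set, sharing one null ensemble."""

    length: LengthStats
    aa: pd.DataFrame
    gc: pd.DataFrame
    rscu: pd.DataFrame
    starts: pd.Series
    stops: pd.Series
    profile_gc: pd.Series
    n_stats: int
    n_flagged: int

    @property
    def flag_rate(self) -> float:
        return self.n_flagged / self.n_stats


def composition_battery(
    sig_set: Iterable[str],
    profile: GenomeProfile,
    n_sets: int = 1000,
    seed: int = 0,
    positional_profile: bool = True,
) -> CompositionBattery:
    """Run every composition analysis with a single shared set of random sets."""
    sig = list(sig_set)
    idx = profile.indices(sig)
    rng = np.random.default_rng(seed)
    null_idx = _random_index_sets(profile, idx.size, n_sets, rng)
    length = protein_length_stats(sig, profile, n_sets, seed, null_idx)
    aa = compare_aa_frequencies(sig, profile, n_sets, seed, null_idx)
    gc = compare_gc_windows(sig, profile, n_sets, seed, null_idx)
    rscu_df = compare_rscu(sig, profile, n_sets, seed, null_idx)
    starts, stops = start_stop_usage(sig, profile)
    prof = (
        gc_positional_profile(sig, profile)
        if positional_profile
        else pd.Series(dtype=float, name="gc_percent")
    )
    flags = [length.comparison.significant]
    n_stats = 1
    for df in (aa, gc, rscu_df):
        valid = df["z"].notna()
        n_stats += int(valid.sum())
        flags.extend(df.loc[valid, "significant"].tolist())
    return CompositionBattery(
        length, aa, gc, rscu_df, starts, stops, prof, n_stats, int(np.sum(flags))
    )
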