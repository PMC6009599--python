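"""Translational-efficiency contrasts, gene classification and partitioning.

Translational efficiency (TE) of a transcript is its abundance in a
ribosome-associated fraction relative to its abundance in total RNA; on
the GEM's log2 scale that is a simple column subtraction.  Heat-shock
contrasts are formed per biological replicate (42 °C minus 30 °C within
the same culture, respecting the paired design) and fed to rank products.
Genes are then classified by combining the TE call with the
transcription-level call, and transcripts are additionally examined for
redistribution between the monosome and polysome pools.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .gem_pipeline import GEM
from .rank_products import RPResult, call_significant, estimate_pfp

GENE_CLASSES = (
    "potentiated",
    "te_up_t_unchanged",
    "te_up_t_down",
    "te_down",
    "t_up_only",
    "t_down_only",
    "none",
)


@dataclass
class TETable:
    """Per-gene, per-(temperature, replicate) log2 TE values for one contrast."""

    genes: list[str]
    values: pd.DataFrame  # columns: MultiIndex (temperature_c, replicate)
    numerator: str
    denominator: str

    def contrast(self) -> tuple[np.ndarray, list[int]]:
        """Paired per-replicate heat-shock differences TE(42) - TE(30)."""
        temps = sorted({t for t, _ in self.values.columns})
        if temps != [30, 42]:
            raise ValueError(f"both temperatures required, found {temps}")
        reps = sorted({r for t, r in self.values.columns if t == 30})
        reps42 = sorted({r for t, r in self.values.columns if t == 42})
        if reps != reps42:
            raise ValueError(f"replicates differ between temperatures: {reps} vs {reps42}")
        fc = np.column_stack(
            [self.values[(42, r)].to_numpy() - self.values[(30, r)].to_numpy() for r in reps]
        )
        return fc, reps


def compute_te(gem: GEM, numerator_fraction: str, denominator_fraction: str) -> TETable:
    """TE(g, r, t) = gem[g, numerator(r, t)] - gem[g, denominator(r, t)].

    Subtraction because the GEM holds log2 values; on the natural scale
    this is the fraction-abundance ratio.  With numerator = monosome and
    denominator = polysome it yields the monosome-partitioning contrast
    instead of a TE proper.
    """
    pairs = {
        (s.temperature_c, s.replicate) for s in gem.samples if s.fraction == denominator_fraction
    }
    num_pairs = {
        (s.temperature_c, s.replicate) for s in gem.samples if s.fraction == numerator_fraction
    }
    if not pairs and not num_pairs:
        raise KeyError(f"GEM contains neither {numerator_fraction} nor {denominator_fraction} samples")
    for t, r in sorted(pairs | num_pairs):
        for frac in (numerator_fraction, denominator_fraction):
            try:
                gem.sample_index(frac, t, r)
            except KeyError:
                raise KeyError(
                    f"missing sample: fraction={frac}, temperature={t}, replicate={r}"
                ) from None
    cols = {}
    for t, r in sorted(pairs):
        cols[(t, r)] = gem.column(numerator_fraction, t, r) - gem.column(
            denominator_fraction, t, r
        )
    values = pd.DataFrame(cols, index=gem.row_ids)
    values.columns = pd.MultiIndex.from_tuples(values.columns)
    return TETable(list(gem.row_ids), values, numerator_fraction, denominator_fraction)


def differential_te(te: TETable, n_perm: int = 1000, seed: int = 0) -> RPResult:
    """Rank-product test of per-replicate heat-shock TE changes."""
    fc, _ = te.contrast()
    return estimate_pfp(fc, te.genes, n_perm=n_perm, seed=seed)


def abundance_contrast(gem: GEM, fraction: str) -> tuple[np.ndarray, list[str]]:
    """Paired per-replicate 42-vs-30 log2 fold changes within one fraction."""
    reps30 = sorted(s.replicate for s in gem.samples if s.fraction == fraction and s.temperature_c == 30)
    reps42 = sorted(s.replicate for s in gem.samples if s.fraction == fraction and s.temperature_c == 42)
    if not reps30 or reps30 != reps42:
        raise ValueError(
            f"fraction {fraction!r}: paired replicates at both temperatures required "
            f"(30 °C: {reps30}, 42 °C: {reps42})"
        )
    fc = np.column_stack(
        [gem.column(fraction, 42, r) - gem.column(fraction, 30, r) for r in reps30]
    )
    return fc, list(gem.row_ids)


def differential_abundance(gem: GEM, fraction: str, n_perm: int = 1000, seed: int = 0) -> RPResult:
    fc, genes = abundance_contrast(gem, fraction)
    return estimate_pfp(fc, genes, n_perm=n_perm, seed=seed)


def classify_genes(
    all_genes: Iterable[str],
    te_up: set[str],
    te_down: set[str],
    t_up: set[str],
    t_down: set[str],
) -> pd.Series:
    """Combine TE and transcription calls into mutually exclusive classes.

    potentiated            TE up and transcription up
    te_up_t_unchanged      TE up, transcription not significant
    te_up_t_down           TE up despite transcriptional down-regulation
    te_down                TE down (rare)
    t_up_only / t_down_only transcription-only changes
    none                   everything else
    """
    contradiction = te_up & te_down
    if contradiction:
        raise ValueError(f"genes called TE-up and TE-down simultaneously: {sorted(contradiction)[:5]}")
    if t_up & t_down:
        warnings.warn(f"{len(t_up & t_down)} genes called up and down transcriptionally")
    out = {}
    for g in all_genes:
        if g in te_up:
            if g in t_up:
                cls = "potentiated"
            elif g in t_down:
                cls = "te_up_t_down"
            else:
                cls = "te_up_t_unchanged"
        elif g in te_down:
            cls = "te_down"
        elif g in t_up:
            cls = "t_up_only"
        elif g in t_down:
            cls = "t_down_only"
        else:
            cls = "none"
        out[g] = cls
    return pd.Series(out, name="gene_class")


def venn_partition(sets: Mapping[str, set[str]]) -> pd.DataFrame:
    """Counts for every intersection region of the given sets.

    For four sets (the polysome-up / TE-up / T-up / T-down partition) this
    is the 15-region table behind a four-way Venn diagram; region counts
    sum to the size of the union.  Rows carry one boolean column per set
    plus the member count; all 2^n - 1 regions are listed, empty ones with
    count 0.
    """
    names = list(sets)
    if not names:
        raise ValueError("at least one set required")
    rows = []
    universe = set().union(*sets.values())
    for size in range(len(names), 0, -1):
        for combo in combinations(names, size):
            inside = set(universe)
            for n in combo:
                inside &= sets[n]
            for n in names:
                if n not in combo:
                    inside -= sets[n]
            rows.append({**{n: n in combo for n in names}, "count": len(inside)})
    return pd.DataFrame(rows, columns=names + ["count"])


@dataclass
class MonosomeReport:
    """Rank-product result for the mono-vs-poly contrast plus its associations."""

    result: RPResult
    significant: set[str]
    n_significant: int
    frac_orf_lt_1000: float
    abundance: pd.DataFrame  # index temperature; columns sig_mean, genome_mean, wilcoxon_p


def monosome_partitioning(
    gem: GEM,
    orf_lengths: Mapping[str, int],
    n_perm: int = 1000,
    seed: int = 0,
    threshold: float = 0.1,
) -> MonosomeReport:
    """Which transcripts redistribute between monosome and polysome pools.

    The contrast is a difference of differences per replicate:
    [mono(42) - poly(42)] - [mono(30) - poly(30)], tested by rank
    products.  For the significant genes (either direction) the report
    gives the fraction with ORF < 1000 nt and their mean total-RNA
    abundance against the genome mean at each temperature, with one-tailed
    Wilcoxon rank-sum p-values (alternative: significant genes lower).
    """
    te = compute_te(gem, "monosome", "polysome")
    fc, _ = te.contrast()
    result = estimate_pfp(fc, te.genes, n_perm=n_perm, seed=seed)
    up, down = call_significant(result, threshold)
    sig = up | down

    missing = [g for g in sig if g not in orf_lengths]
    if missing:
        raise KeyError(f"ORF length missing for {missing[0]!r} (and {len(missing) - 1} more)")
    if sig:
        frac_short = float(np.mean([orf_lengths[g] < 1000 for g in sig]))
    else:
        frac_short = float("nan")

    gene_index = {g: i for i, g in enumerate(gem.row_ids)}
    sig_idx = [gene_index[g] for g in sorted(sig)]
    rows = []
    for temp in (30, 42):
        reps = sorted(
            s.replicate for s in gem.samples if s.fraction == "total" and s.temperature_c == temp
        )
        means = np.column_stack([gem.column("total", temp, r) for r in reps]).mean(axis=1)
        if sig_idx:
            p = float(mannwhitneyu(means[sig_idx], means, alternative="less").pvalue)
            sig_mean = float(means[sig_idx].mean())
        else:
            p, sig_mean = float("nan"), float("nan")
        rows.append(
            {
                "temperature_c": temp,
                "sig_mean": sig_mean,
                "genome_mean": float(means.mean()),
                "wilcoxon_p": p,
            }
        )
    abundance = pd.DataFrame(rows).set_index("temperature_c")
    return MonosomeReport(result, sig, len(sig), frac_short, abundance)
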