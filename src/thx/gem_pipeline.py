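"""Gene-expression-matrix (GEM) construction from two-channel probe tables.

The processing order is fixed: per-probe log2(sample/reference) ratios with
the negative-value rules, per-array median centering, between-array scale
normalization performed independently within the total-RNA and
ribosome-fraction batches, then control-probe filtering and probe-to-gene
averaging.  The two batches exist because total-RNA and
monosome/polysome-associated RNA pools have genuinely different intensity
distributions; equalizing their spreads jointly would distort both.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import ArraySample, ProbeTable

log = logging.getLogger(__name__)


@dataclass
class GEM:
    """A rows x arrays matrix of log2-ratio values with sample metadata.

    ``stage`` tracks how far the matrix has been processed: ``raw``
    (plain log-ratios), ``centered`` (column medians zero) or
    ``normalized`` (within-batch column MADs equalized).  Rows are probes
    until :func:`filter_and_average` collapses them to genes.
    """

    row_ids: list[str]
    samples: list[ArraySample]
    values: np.ndarray
    stage: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_ids), len(self.samples)):
            raise ValueError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.row_ids)} rows x {len(self.samples)} samples"
            )
        if np.isnan(self.values).any():
            raise ValueError("GEM may not contain missing values")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.row_ids, columns=[s.sample_id for s in self.samples]
        )

    def sample_index(self, fraction: str, temperature_c: int, replicate: int) -> int:
        for i, s in enumerate(self.samples):
            if s.design_key == (fraction, temperature_c, replicate):
                return i
        raise KeyError(
            f"no sample with fraction={fraction}, temperature={temperature_c}, "
            f"replicate={replicate}"
        )

    def column(self, fraction: str, temperature_c: int, replicate: int) -> np.ndarray:
        return self.values[:, self.sample_index(fraction, temperature_c, replicate)]


def compute_log_ratios(table: ProbeTable) -> np.ndarray:
    """Per-probe log2(signal/reference) with the negative-value rules.

    Feature extraction's background subtraction can yield negative (or
    zero) processed intensities, for which the log-ratio is undefined.
    Rules, applied per array: if exactly one channel of a probe is
    non-positive, that channel's value is replaced by the lowest positive
    value of the same channel's distribution on that array; if both
    channels are non-positive the probe's log-ratio is set to 0.  Zeros
    are treated like negatives since log2(0) is equally undefined.

    Raises ``ValueError`` when a replacement is required but the channel
    has no positive value at all on the array.
    """
    if len(table) == 0:
        raise ValueError("probe table is empty")
    s = table.data["signal"].to_numpy(float).copy()
    r = table.data["reference"].to_numpy(float).copy()
    bad_s = s <= 0
    bad_r = r <= 0
    both = bad_s & bad_r
    only_s = bad_s & ~bad_r
    only_r = bad_r & ~bad_s
    if only_s.any():
        pos = s[s > 0]
        if pos.size == 0:
            raise ValueError(
                f"array {table.sample.sample_id}: signal channel has no positive values"
            )
        s[only_s] = pos.min()
    if only_r.any():
        pos = r[r > 0]
        if pos.size == 0:
            raise ValueError(
                f"array {table.sample.sample_id}: reference channel has no positive values"
            )
        r[only_r] = pos.min()
    ratios = np.zeros(len(s))
    ok = ~both
    ratios[ok] = np.log2(s[ok] / r[ok])
    n_replaced = int(only_s.sum() + only_r.sum())
    if n_replaced or both.any():
        log.info(
            "array %s: %d channel values replaced by channel minimum, %d probes zeroed",
            table.sample.sample_id,
            n_replaced,
            int(both.sum()),
        )
    return ratios


def assemble_probe_matrix(tables: Sequence[ProbeTable]) -> tuple[GEM, pd.DataFrame]:
    """Stack per-array log-ratio vectors into a probe-level raw GEM.

    All arrays must share the same probe set and the same probe->gene
    mapping (a uniform platform); otherwise per-gene values would not be
    comparable across arrays.  Returns the raw GEM plus a probe annotation
    frame (gene_id, is_control) indexed by probe_id.
    """
    if not tables:
        raise ValueError("no probe tables supplied")
    first = tables[0].data
    probe_ids = first["probe_id"].tolist()
    info = first.set_index("probe_id")[["gene_id", "is_control"]]
    columns = []
    for t in tables:
        if t.data["probe_id"].tolist() != probe_ids:
            other = t.data.set_index("probe_id")
            if set(other.index) != set(probe_ids):
                raise ValueError(
                    f"array {t.sample.sample_id}: probe set differs — platform must be uniform"
                )
            t = ProbeTable(other.reindex(probe_ids).reset_index(), t.sample)
        ann = t.data.set_index("probe_id")[["gene_id", "is_control"]]
        if not ann.equals(info):
            raise ValueError(
                f"array {t.sample.sample_id}: probe annotation differs — platform must be uniform"
            )
        columns.append(compute_log_ratios(t))
    values = np.column_stack(columns)
    return GEM(probe_ids, [t.sample for t in tables], values, stage="raw"), info


def median_center(gem: GEM) -> GEM:
    """Subtract each array's median so column medians are exactly zero."""
    if gem.stage != "raw":
        raise ValueError(f"median_center expects a raw GEM, got stage={gem.stage!r}")
    med = np.median(gem.values, axis=0, keepdims=True)
    return replace(gem, values=gem.values - med, stage="centered")


def _mad(x: np.ndarray) -> float:
    # unscaled MAD: only ratios of MADs matter here, so the 1.4826
    # consistency factor would cancel
    return float(np.median(np.abs(x - np.median(x))))


def scale_normalize(gem: GEM, batches: Mapping[str, str] | None = None) -> GEM:
    """Equalize column spreads within each normalization batch.

    Each column is divided by its (unscaled) median absolute deviation and
    multiplied by the geometric mean of its batch's column MADs, so that
    columns of a batch share a common MAD while the batch's overall spread
    is preserved.  Batches never influence each other.

    Parameters
    ----------
    batches
        sample_id -> batch label.  Defaults to each sample's intrinsic
        batch (total vs ribosomal).
    """
    if gem.stage != "centered":
        raise ValueError(f"scale_normalize expects a centered GEM, got stage={gem.stage!r}")
    if batches is None:
        batches = {s.sample_id: s.batch for s in gem.samples}
    missing = [s.sample_id for s in gem.samples if s.sample_id not in batches]
    if missing:
        raise ValueError(f"samples missing from batch map: {missing}")
    values = gem.values.copy()
    by_batch: dict[str, list[int]] = {}
    for j, s in enumerate(gem.samples):
        by_batch.setdefault(batches[s.sample_id], []).append(j)
    for label, cols in by_batch.items():
        mads = np.array([_mad(values[:, j]) for j in cols])
        zero = [gem.samples[cols[i]].sample_id for i in np.nonzero(mads == 0)[0]]
        if zero:
            raise ValueError(f"degenerate array (MAD = 0) in batch {label!r}: {zero[0]}")
        target = float(np.exp(np.mean(np.log(mads))))
        for j, mad in zip(cols, mads):
            values[:, j] *= target / mad
    return replace(gem, values=values, stage="normalized")


def filter_and_average(gem: GEM, probe_info: pd.DataFrame) -> GEM:
    """Drop control and unmapped probes, then average probes per gene.

    The per-gene value is the arithmetic mean of that gene's probe
    log-ratios, yielding a single transcript-abundance value per gene per
    array.  The stage label is preserved.
    """
    info = probe_info.reindex(gem.row_ids)
    is_control = info["is_control"].astype(bool).to_numpy()
    gene_id = info["gene_id"].astype(str).to_numpy()
    keep = ~is_control
    n_controls = int(is_control.sum())
    unmapped = keep & (gene_id == "")
    n_unmapped = int(unmapped.sum())
    keep &= gene_id != ""
    log.info(
        "filter_and_average: %d control probes removed, %d unmapped probes dropped, "
        "%d probes retained",
        n_controls,
        n_unmapped,
        int(keep.sum()),
    )
    if not keep.any():
        raise ValueError("no mapped non-control probes remain")
    frame = pd.DataFrame(gem.values[keep], index=gene_id[keep])
    means = frame.groupby(level=0).mean().sort_index()
    return GEM(list(means.index), gem.samples, means.to_numpy(), stage=gem.stage)


def build_gem(tables: Sequence[ProbeTable], batches: Mapping[str, str] | None = None) -> GEM:
    """Full pipeline: log-ratios -> center -> batch scale-normalize -> average.

    Deterministic: identical inputs give a bit-identical gene-level GEM.
    """
    raw, info = assemble_probe_matrix(tables)
    centered = median_center(raw)
    normalized = scale_normalize(centered, batches)
    return filter_and_average(normalized, info)
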