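"""Occupancy scoring for pooled barcode ChIP screens.

The quantification chain, per replicate screen and timepoint:

1. *Absence filter* — barcodes with fewer than a fixed fraction of the
   input sample's total reads (default 0.0025%) are treated as absent from
   the pool and excluded.
2. *Median normalization* — each retained barcode's count is divided by the
   median retained count of its sample, so samples of different depth are
   comparable.
3. *IP/input ratio* — the median-normalized IP score divided by the
   median-normalized input score is the per-strain occupancy score.
4. *Replicate averaging* — ratios are averaged across replicate screens per
   timepoint, over the strains retained in every replicate's input at both
   timepoints (the overlapping-ORF intersection).
5. *log2 fold-change and classification* — mean ratios are expressed as
   log2 fold-changes against a baseline (by default the median over the
   pooled wild-type control barcodes) and thresholded at +/- tau
   (default 1.25) into the four hit classes ``down_both``, ``up_both``,
   ``down_40_only``, ``down_80_only``, with ``other`` for the rest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from repliid.barcode_io import BarcodeMap, SampleCounts

HIT_CLASSES = ("down_both", "up_both", "down_40_only", "down_80_only", "other")


@dataclass
class ScreenConfig:
    """Thresholds and conventions of the scoring chain.

    absence_fraction
        Fraction of an input sample's total reads below which a barcode is
        considered absent (default 2.5e-5, i.e. 0.0025%).  "Below" is
        strict: a barcode exactly at the cutoff is retained.
    hit_threshold
        tau, in log2 units, for hit classification (default 1.25).
    baseline_policy
        What the fold-change is relative to: ``wildtype_median`` (median
        mean-ratio over the wild-type control barcodes, per timepoint),
        ``all_median``, or ``none`` (baseline 1).
    replicate_combine
        ``mean_of_ratios`` (arithmetic mean of raw ratios, then log2) or
        ``mean_of_logs`` (geometric mean).
    correlation_method
        ``pearson_log`` (Pearson on log2 ratios) or ``spearman_raw``.
    """

    absence_fraction: float = 2.5e-5
    hit_threshold: float = 1.25
    baseline_policy: str = "wildtype_median"
    replicate_combine: str = "mean_of_ratios"
    correlation_method: str = "pearson_log"

    def __post_init__(self):
        if not (0 <= self.absence_fraction < 1):
            raise ValueError("absence_fraction must be in [0, 1)")
        if self.hit_threshold <= 0:
            raise ValueError("hit_threshold must be positive")
        if self.baseline_policy not in ("wildtype_median", "all_median", "none"):
            raise ValueError(f"unknown baseline_policy {self.baseline_policy!r}")
        if self.replicate_combine not in ("mean_of_ratios", "mean_of_logs"):
            raise ValueError(f"unknown replicate_combine {self.replicate_combine!r}")
        if self.correlation_method not in ("pearson_log", "spearman_raw"):
            raise ValueError(f"unknown correlation_method {self.correlation_method!r}")


def _counts_mapping(counts: SampleCounts | Mapping[str, int]) -> Mapping[str, int]:
    return counts.counts if isinstance(counts, SampleCounts) else counts


def filter_absent(input_counts: SampleCounts, cfg: ScreenConfig) -> set[str]:
    """Barcodes retained in an input sample: count >= absence_fraction * total."""
    if input_counts.sample.role != "input":
        raise ValueError("absence filter applies to input samples only")
    total = input_counts.total_reads
    if total == 0:
        raise ValueError(f"empty input sample {input_counts.sample.sample_id!r}")
    cutoff = cfg.absence_fraction * total
    return {bc for bc, n in input_counts.counts.items() if n >= cutoff}


def median_normalize(
    counts: SampleCounts | Mapping[str, int], retained: Iterable[str]
) -> pd.Series:
    """Divide each retained barcode's count by the median retained count.

    The median uses midpoint interpolation for even-sized sets, so the
    median of the returned scores is 1.
    """
    cmap = _counts_mapping(counts)
    retained = list(retained)
    if not retained:
        raise ValueError("retained barcode set is empty")
    vals = pd.Series({bc: cmap[bc] for bc in retained}, dtype=float)
    med = float(vals.median())
    if med == 0:
        raise ValueError("degenerate sample: median retained count is 0")
    return vals / med


def ip_over_input(ip_scores: pd.Series, input_scores: pd.Series) -> pd.Series:
    """Per-barcode occupancy ratio over the common barcode set.

    Barcodes with zero IP signal get ratio 0; a zero input score cannot
    occur for a retained barcode (the absence filter guarantees a positive
    count), so it is treated as an internal error.
    """
    common = ip_scores.index.intersection(input_scores.index)
    inp = input_scores.loc[common]
    if (inp <= 0).any():
        raise AssertionError("retained barcode with non-positive input score")
    return ip_scores.loc[common] / inp


def replicate_ratios(
    ip_counts: SampleCounts, input_counts: SampleCounts, cfg: ScreenConfig
) -> tuple[pd.Series, set[str]]:
    """Full per-replicate chain: filter on the input, normalize both
    samples over the retained set, divide.  Returns (ratios, retained)."""
    retained = filter_absent(input_counts, cfg)
    if not retained:
        raise ValueError(
            f"no barcodes retained in {input_counts.sample.sample_id!r}"
        )
    ip_scores = median_normalize(ip_counts, retained)
    input_scores = median_normalize(input_counts, retained)
    return ip_over_input(ip_scores, input_scores), retained


def merge_replicates(
    ratio_tables: Mapping[tuple[int, int], pd.Series], cfg: ScreenConfig
) -> pd.DataFrame:
    """Average ratios across replicates per timepoint.

    ``ratio_tables`` maps (timepoint, replicate) to per-barcode ratios.  A
    barcode survives only if present in every table (retained in every
    replicate's input at both timepoints).  Columns of the result are the
    sorted timepoints; values are arithmetic means of the raw ratios (or
    geometric means under ``mean_of_logs``).
    """
    if not ratio_tables:
        raise ValueError("no ratio tables")
    timepoints = sorted({t for t, _ in ratio_tables})
    for t in timepoints:
        reps = [r for tt, r in ratio_tables if tt == t]
        if len(reps) < 2:
            raise ValueError(f"need >= 2 replicates per timepoint, got {len(reps)} at t={t}")

    common = None
    for series in ratio_tables.values():
        idx = series.index
        common = idx if common is None else common.intersection(idx)
    if common is None or len(common) == 0:
        raise ValueError("no overlapping barcodes across replicates")

    out = {}
    for t in timepoints:
        cols = [s.loc[common] for (tt, _), s in sorted(ratio_tables.items()) if tt == t]
        mat = pd.concat(cols, axis=1)
        if cfg.replicate_combine == "mean_of_ratios":
            out[t] = mat.mean(axis=1)
        else:
            # geometric mean; any zero ratio forces a zero mean
            zero = (mat == 0).any(axis=1)
            gm = np.exp(np.log(mat.where(mat > 0)).mean(axis=1)).fillna(0.0)
            gm[zero] = 0.0
            out[t] = gm
    return pd.DataFrame(out)


def compute_baseline(
    mean_ratios: pd.Series, wildtype_barcodes: Iterable[str], policy: str
) -> float:
    if policy == "none":
        return 1.0
    if policy == "all_median":
        return float(mean_ratios.median())
    wt = mean_ratios.index.intersection(pd.Index(set(wildtype_barcodes)))
    if len(wt) == 0:
        raise ValueError("baseline_policy=wildtype_median but no wild-type barcodes survive")
    return float(mean_ratios.loc[wt].median())


def log2_fold_change(
    mean_ratios: pd.DataFrame,
    wildtype_barcodes: Iterable[str] = (),
    baseline_policy: str = "wildtype_median",
) -> tuple[pd.DataFrame, dict[int, float], pd.DataFrame]:
    """log2 of mean ratios against the per-timepoint baseline.

    Zero mean ratios are floored to the smallest positive mean ratio of the
    same timepoint before taking log2, and flagged.  Returns
    ``(log2fc, baselines, floored_flags)``.
    """
    wildtype_barcodes = set(wildtype_barcodes)
    fcs, baselines, floored = {}, {}, {}
    for t in mean_ratios.columns:
        col = mean_ratios[t].astype(float)
        if (col < 0).any():
            raise ValueError("negative ratio")
        b = compute_baseline(col, wildtype_barcodes, baseline_policy)
        if b <= 0:
            raise ValueError(f"non-positive baseline at t={t}")
        pos = col[col > 0]
        if len(pos) == 0:
            raise ValueError(f"all ratios zero at t={t}")
        eps = float(pos.min())
        flag = col == 0
        vals = col.where(~flag, eps)
        fcs[t] = np.log2(vals / b)
        baselines[int(t)] = b
        floored[t] = flag
    return pd.DataFrame(fcs), baselines, pd.DataFrame(floored)


def classify_mutants(log2fc_t40: float, log2fc_t80: float, tau: float = 1.25) -> str:
    """Assign one of the five hit classes from the two log2 fold-changes.

    All threshold comparisons are strict; a gene exactly at +/- tau at a
    timepoint does not count as changed there.
    """
    f40, f80 = log2fc_t40, log2fc_t80
    if not (math.isfinite(f40) and math.isfinite(f80)):
        raise ValueError("log2 fold-changes must be finite")
    if f40 < -tau and f80 < -tau:
        return "down_both"
    if f40 > tau and f80 > tau:
        return "up_both"
    if f40 < -tau:  # f80 >= -tau here
        return "down_40_only"
    if abs(f40) <= tau and f80 < -tau:
        return "down_80_only"
    return "other"


def classify_table(log2fc: pd.DataFrame, tau: float = 1.25) -> pd.Series:
    """Vectorized :func:`classify_mutants` over a two-timepoint table."""
    t40, t80 = sorted(log2fc.columns)
    return pd.Series(
        [classify_mutants(a, b, tau) for a, b in zip(log2fc[t40], log2fc[t80])],
        index=log2fc.index,
        dtype="object",
    )


def replicate_correlation(
    rep1: pd.Series, rep2: pd.Series, method: str = "pearson_log"
) -> float:
    """Reproducibility R between two replicate ratio tables.

    Pearson on log2 ratios by default (zero ratios dropped); Spearman on raw
    ratios as an option.  NaN when either vector is constant.
    """
    common = rep1.index.intersection(rep2.index)
    a = rep1.loc[common].astype(float)
    b = rep2.loc[common].astype(float)
    if method == "pearson_log":
        keep = (a > 0) & (b > 0)
        a, b = np.log2(a[keep]), np.log2(b[keep])
    if len(a) < 3:
        raise ValueError("need >= 3 shared genes for a correlation")
    if a.std(ddof=0) == 0 or b.std(ddof=0) == 0:
        return float("nan")
    if method == "pearson_log":
        return float(stats.pearsonr(a, b).statistic)
    return float(stats.spearmanr(a, b).statistic)


@dataclass
class ScreenResult:
    """Outcome of :func:`score_screen`.

    ``scores`` is the per-gene table (mutant genes only): mean ratios and
    log2 fold-changes at both timepoints, hit class, floor flags.
    ``info`` carries run diagnostics: retained-barcode counts per sample,
    baselines per timepoint, replicate correlations, class tallies.
    """

    scores: pd.DataFrame
    info: dict = field(default_factory=dict)

    def class_tallies(self) -> dict[str, int]:
        tally = {c: 0 for c in HIT_CLASSES}
        tally.update(self.scores["hit_class"].value_counts().to_dict())
        return tally


def score_screen(
    samples: Sequence[SampleCounts],
    barcode_map: BarcodeMap,
    cfg: ScreenConfig | None = None,
) -> ScreenResult:
    """Run the whole scoring chain over one screen's samples.

    ``samples`` must contain an IP and an input sample for each
    (timepoint, replicate) combination, with exactly two distinct
    timepoints and at least two replicates.
    """
    cfg = cfg or ScreenConfig()
    by_key: dict[tuple[str, int, int], SampleCounts] = {}
    for s in samples:
        key = (s.sample.role, s.sample.timepoint, s.sample.replicate)
        if key in by_key:
            raise ValueError(f"duplicate sample for {key}")
        by_key[key] = s
    pairs = sorted({(t, r) for role, t, r in by_key})
    timepoints = sorted({t for t, _ in pairs})
    if len(timepoints) != 2:
        raise ValueError(f"need exactly two timepoints, got {timepoints}")

    ratio_tables: dict[tuple[int, int], pd.Series] = {}
    retained_counts: dict[str, int] = {}
    for t, r in pairs:
        try:
            ip = by_key[("IP", t, r)]
            inp = by_key[("input", t, r)]
        except KeyError as exc:
            raise ValueError(f"missing IP or input sample at t={t} replicate {r}") from exc
        ratios, retained = replicate_ratios(ip, inp, cfg)
        ratio_tables[(t, r)] = ratios
        retained_counts[inp.sample.sample_id] = len(retained)

    merged = merge_replicates(ratio_tables, cfg)

    wt_mask = barcode_map.entries["strain_class"] == "wildtype"
    wt_barcodes = set(barcode_map.entries.loc[wt_mask, "barcode"])
    log2fc, baselines, floored = log2_fold_change(
        merged, wt_barcodes, cfg.baseline_policy
    )

    # wild-type barcodes feed the baseline but are never emitted as genes
    mut_barcodes = [bc for bc in merged.index if bc not in wt_barcodes]
    if not mut_barcodes:
        raise ValueError("no mutant barcodes survive the overlap")
    gene_of = dict(zip(barcode_map.entries["barcode"], barcode_map.entries["gene"]))
    t40, t80 = timepoints
    n_reps = len({r for _, r in pairs})
    scores = pd.DataFrame(
        {
            "gene": [gene_of[bc] for bc in mut_barcodes],
            "mean_ratio_t40": merged.loc[mut_barcodes, t40].to_numpy(),
            "mean_ratio_t80": merged.loc[mut_barcodes, t80].to_numpy(),
            "log2fc_t40": log2fc.loc[mut_barcodes, t40].to_numpy(),
            "log2fc_t80": log2fc.loc[mut_barcodes, t80].to_numpy(),
            "floored_t40": floored.loc[mut_barcodes, t40].to_numpy(),
            "floored_t80": floored.loc[mut_barcodes, t80].to_numpy(),
        }
    ).set_index("gene")
    scores["hit_class"] = [
        classify_mutants(a, b, cfg.hit_threshold)
        for a, b in zip(scores["log2fc_t40"], scores["log2fc_t80"])
    ]
    scores["n_replicates_used"] = n_reps

    correlations = {}
    for t in timepoints:
        reps = sorted(r for tt, r in ratio_tables if tt == t)
        if len(reps) == 2:
            correlations[int(t)] = replicate_correlation(
                ratio_tables[(t, reps[0])],
                ratio_tables[(t, reps[1])],
                cfg.correlation_method,
            )

    result = ScreenResult(
        scores=scores,
        info={
            "retained_per_input": retained_counts,
            "baselines": baselines,
            "replicate_correlation": correlations,
            "n_scored": len(scores),
            "timepoints": [int(t) for t in timepoints],
            "config": cfg,
        },
    )
    result.info["class_tallies"] = result.class_tallies()
    return result
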