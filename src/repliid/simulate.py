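"""Synthetic screens with known ground truth.

The generator emulates a pooled barcode ChIP screen: a library of barcoded
mutant and wild-type strains with log-normal pool abundances, per-strain
occupancy multipliers by hit class, multinomial read sampling at a chosen
depth, per-replicate log-normal occupancy noise, and i.i.d. substitution
sequencing errors.  Ground truth (abundances, multipliers, true classes)
is returned alongside, so pipeline recovery can be scored exactly.

Two output levels exist: :func:`simulate_screen_counts` produces per-sample
barcode counts directly (fast; sequencing error enters as binomial loss of
reads whose anchor or barcode is corrupted), and :func:`simulate_screen`
writes full FASTQ files that the counting stage can consume.  With
well-separated barcodes the two agree up to sampling noise, since a
corrupted barcode almost never lands on another library barcode.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from repliid.barcode_io import BarcodeMap, SampleCounts, SampleMeta

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: default hit-class occupancy effects, log2 units at (t40, t80)
DEFAULT_CLASS_EFFECTS = {
    "down_both": (-2.0, -2.0),
    "up_both": (2.0, 2.0),
    "down_40_only": (-2.0, 0.0),
    "down_80_only": (0.0, -2.0),
}

#: default class proportions, echoing the hit structure of a real screen
#: (~15% depleted at both timepoints, ~4% enriched, ~5% each single-timepoint)
DEFAULT_CLASS_PROPORTIONS = {
    "down_both": 0.15,
    "up_both": 0.04,
    "down_40_only": 0.05,
    "down_80_only": 0.05,
}


@dataclass
class SimulationParams:
    """Everything the screen generator needs.

    The library defaults mirror the scale of a genome-wide pool: ~4500
    barcoded mutants plus ~1100 barcoded wild types carrying 20-bp barcodes.
    ``abundance_sd`` is the natural-log SD of per-strain pool abundances;
    ``replicate_noise_sd`` the natural-log SD of the per-replicate,
    per-strain multiplicative occupancy noise applied to IP samples.
    ``base_error_rate`` is the per-base substitution probability.
    """

    n_mutants: int = 4500
    n_wildtypes: int = 1100
    barcode_length: int = 20
    min_pairwise_hamming: int = 3
    abundance_sd: float = 0.5
    class_proportions: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS))
    class_effects: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_EFFECTS))
    read_depth: int = 2_000_000
    base_error_rate: float = 0.002
    replicate_noise_sd: float = 0.1
    n_replicates: int = 2
    timepoints: tuple = (40, 80)
    anchor: str = "GTACGCTGCAGGTCGAC"
    read_length: int = 50
    seed: int | None = None

    def __post_init__(self):
        if sum(self.class_proportions.values()) > 1 + 1e-9:
            raise ValueError("class proportions must sum to <= 1")
        if self.read_depth <= 0:
            raise ValueError("read_depth must be positive")
        if not (0 <= self.base_error_rate < 0.25):
            raise ValueError("base_error_rate must be in [0, 0.25)")
        unknown = set(self.class_proportions) - set(self.class_effects)
        if unknown:
            raise ValueError(f"classes without effects: {sorted(unknown)}")
        needed = len(self.anchor) + self.barcode_length
        if self.read_length < needed:
            raise ValueError(f"read_length must be >= {needed}")


def standard_recovery_params(**overrides) -> SimulationParams:
    """The standard parameter-recovery scenario: a 500-mutant + 100-wild-type
    pool, 10% of mutants depleted at both timepoints (log2 effect -2), 5%
    enriched (+2), abundance SD 0.5, replicate noise SD 0.1, substitution
    rate 0.002, two replicate screens at 2e6 reads per sample."""
    params = dict(
        n_mutants=500,
        n_wildtypes=100,
        class_proportions={"down_both": 0.10, "up_both": 0.05},
        class_effects={"down_both": (-2.0, -2.0), "up_both": (2.0, 2.0)},
        abundance_sd=0.5,
        replicate_noise_sd=0.1,
        base_error_rate=0.002,
        read_depth=2_000_000,
        n_replicates=2,
    )
    params.update(overrides)
    return SimulationParams(**params)


def null_params(**overrides) -> SimulationParams:
    """The same pool with no injected effects (every mutant truly 'other')."""
    return standard_recovery_params(class_proportions={}, **overrides)


# ---------------------------------------------------------------------------
# library generation

def _sample_separated_barcodes(n: int, L: int, min_dist: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random barcodes, rejecting any within ``min_dist`` of an
    accepted one (distinctness is always enforced)."""
    min_dist = max(1, min_dist)
    if 4**min(L, 30) < 4 * n:
        raise ValueError(f"barcode space too small for {n} barcodes of length {L}")
    accepted = np.empty((n, L), dtype=np.uint8)
    n_ok = 0
    tries = 0
    max_tries = 200 * n + 1000
    while n_ok < n:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {n} barcodes at min Hamming distance {min_dist}; "
                f"increase barcode_length"
            )
        cand = rng.integers(0, 4, size=L, dtype=np.uint8)
        if n_ok and int((accepted[:n_ok] != cand).sum(axis=1).min()) < min_dist:
            continue
        accepted[n_ok] = cand
        n_ok += 1
    return accepted


def _codes_to_strings(codes: np.ndarray) -> list[str]:
    return [row.tobytes().decode("ascii") for row in _BASES[codes]]


def generate_barcode_library(
    params: SimulationParams, seed: int | None = None
) -> tuple[BarcodeMap, pd.DataFrame]:
    """Build the barcode library and its ground truth.

    Mutants receive hit classes by the configured proportions (counts are
    rounded, assignment is random); each class carries fixed occupancy
    multipliers ``2**effect`` at both timepoints.  Wild types always have
    multiplier 1.  Abundances are log-normal with SD ``abundance_sd``.
    Deterministic given the seed.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    n = params.n_mutants + params.n_wildtypes
    codes = _sample_separated_barcodes(n, params.barcode_length, params.min_pairwise_hamming, rng)
    barcodes = _codes_to_strings(codes)

    strain_ids = [f"mut{i:05d}" for i in range(params.n_mutants)] + [
        f"wt{i:05d}" for i in range(params.n_wildtypes)
    ]
    genes = [f"GENE{i:05d}" for i in range(params.n_mutants)] + ["WT"] * params.n_wildtypes
    classes = ["mutant"] * params.n_mutants + ["wildtype"] * params.n_wildtypes
    bmap = BarcodeMap(
        pd.DataFrame(
            {"barcode": barcodes, "strain_id": strain_ids, "gene": genes, "strain_class": classes}
        )
    )

    true_class = np.array(["other"] * params.n_mutants, dtype=object)
    order = rng.permutation(params.n_mutants)
    start = 0
    for cls, prop in params.class_proportions.items():
        n_cls = int(round(prop * params.n_mutants))
        true_class[order[start : start + n_cls]] = cls
        start += n_cls

    m40 = np.ones(n)
    m80 = np.ones(n)
    for i, cls in enumerate(true_class):
        if cls != "other":
            e40, e80 = params.class_effects[cls]
            m40[i], m80[i] = 2.0**e40, 2.0**e80
    abundance = np.exp(rng.normal(0.0, params.abundance_sd, size=n))

    truth = pd.DataFrame(
        {
            "strain_id": strain_ids,
            "gene": genes,
            "strain_class": classes,
            "true_class": list(true_class) + ["wildtype"] * params.n_wildtypes,
            "abundance": abundance,
            "m_t40": m40,
            "m_t80": m80,
        }
    )
    return bmap, truth


# ---------------------------------------------------------------------------
# screen simulation

def _sample_layout(params: SimulationParams) -> list[SampleMeta]:
    metas = []
    for rep in range(1, params.n_replicates + 1):
        for t in params.timepoints:
            for role in ("input", "IP"):
                metas.append(SampleMeta(f"{role}_t{t}_r{rep}", role, int(t), rep))
    return metas


def _expected_proportions(
    truth: pd.DataFrame, meta: SampleMeta, rep_noise: np.ndarray
) -> np.ndarray:
    w = truth["abundance"].to_numpy(copy=True)
    if meta.role == "IP":
        m = truth[f"m_t{meta.timepoint}"].to_numpy()
        w = w * m * rep_noise
    return w / w.sum()


def simulate_screen_counts(
    bmap: BarcodeMap,
    truth: pd.DataFrame,
    params: SimulationParams,
    seed: int | None = None,
) -> list[SampleCounts]:
    """Draw per-sample barcode counts directly (no FASTQ round trip).

    Input proportions follow abundances; IP proportions additionally carry
    the occupancy multipliers and per-replicate log-normal noise (one draw
    per strain per replicate, shared between timepoints).  Counts are
    multinomial at ``read_depth``.  Sequencing error enters as binomial
    thinning with per-read survival ``(1-e)**(anchor+barcode length)`` —
    under exact matching a read with any substitution in its anchor or
    barcode goes unassigned.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    n = len(truth)
    keep_p = (1.0 - params.base_error_rate) ** (len(params.anchor) + params.barcode_length)
    rep_noise = {
        rep: np.exp(rng.normal(0.0, params.replicate_noise_sd, size=n))
        for rep in range(1, params.n_replicates + 1)
    }
    out = []
    for meta in _sample_layout(params):
        p = _expected_proportions(truth, meta, rep_noise[meta.replicate])
        raw = rng.multinomial(params.read_depth, p)
        assigned = rng.binomial(raw, keep_p)
        counts = dict(zip(bmap.barcodes, (int(x) for x in assigned)))
        total_assigned = int(assigned.sum())
        sc = SampleCounts(
            sample=meta,
            counts=counts,
            total_reads=params.read_depth,
            assigned_reads=total_assigned,
            unassigned_reads=params.read_depth - total_assigned,
        )
        sc.validate()
        out.append(sc)
    return out


def _emit_fastq(
    path: Path,
    barcode_codes: np.ndarray,
    read_counts: np.ndarray,
    params: SimulationParams,
    rng: np.random.Generator,
    compress: bool,
) -> None:
    """Write one sample's reads: anchor + barcode + random filler, with
    i.i.d. substitution errors over the whole read."""
    anchor_codes = np.frombuffer(params.anchor.encode(), dtype=np.uint8)
    anchor_idx = np.searchsorted(_BASES, anchor_codes)  # ACGT are sorted bytes
    L = params.barcode_length
    n_fill = params.read_length - len(anchor_codes) - L
    depth = int(read_counts.sum())
    strain_per_read = np.repeat(np.arange(len(read_counts)), read_counts)
    rng.shuffle(strain_per_read)

    qual = "I" * params.read_length
    opener = (lambda p: gzip.open(p, "wt", compresslevel=2)) if compress else (lambda p: open(p, "wt"))
    chunk = 250_000
    read_id = 0
    with opener(path) as fh:
        for lo in range(0, depth, chunk):
            idx = strain_per_read[lo : lo + chunk]
            m = len(idx)
            reads = np.empty((m, params.read_length), dtype=np.uint8)
            reads[:, : len(anchor_idx)] = anchor_idx
            reads[:, len(anchor_idx) : len(anchor_idx) + L] = barcode_codes[idx]
            if n_fill:
                reads[:, len(anchor_idx) + L :] = rng.integers(0, 4, size=(m, n_fill), dtype=np.uint8)
            if params.base_error_rate > 0:
                err = rng.random((m, params.read_length)) < params.base_error_rate
                shift = rng.integers(1, 4, size=int(err.sum()), dtype=np.uint8)
                reads[err] = (reads[err] + shift) % 4
            seq_bytes = _BASES[reads].tobytes()
            lines = []
            for i in range(m):
                s = seq_bytes[i * params.read_length : (i + 1) * params.read_length].decode("ascii")
                lines.append(f"@r{read_id}\n{s}\n+\n{qual}\n")
                read_id += 1
            fh.write("".join(lines))


def simulate_screen(
    bmap: BarcodeMap,
    truth: pd.DataFrame,
    params: SimulationParams,
    outdir: str | Path,
    seed: int | None = None,
    compress: bool = True,
) -> pd.DataFrame:
    """Write FASTQ files for every sample plus the sample sheet, barcode
    map, and truth table under ``outdir``.  Returns the sample sheet.

    The same generative model as :func:`simulate_screen_counts`, but reads
    are materialised: each read is anchor + barcode + random filler with
    i.i.d. substitutions at ``base_error_rate`` over every base.
    Deterministic given the seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(params.seed if seed is None else seed)
    n = len(truth)
    barcode_codes = np.searchsorted(
        _BASES, np.frombuffer("".join(bmap.barcodes).encode(), dtype=np.uint8)
    ).reshape(n, params.barcode_length).astype(np.uint8)
    rep_noise = {
        rep: np.exp(rng.normal(0.0, params.replicate_noise_sd, size=n))
        for rep in range(1, params.n_replicates + 1)
    }
    rows = []
    ext = ".fastq.gz" if compress else ".fastq"
    for meta in _sample_layout(params):
        p = _expected_proportions(truth, meta, rep_noise[meta.replicate])
        raw = rng.multinomial(params.read_depth, p)
        fq = outdir / f"{meta.sample_id}{ext}"
        _emit_fastq(fq, barcode_codes, raw, params, rng, compress)
        rows.append(
            {
                "sample_id": meta.sample_id,
                "fastq_path": str(fq),
                "role": meta.role,
                "timepoint": meta.timepoint,
                "replicate": meta.replicate,
            }
        )
    sheet = pd.DataFrame(rows)
    sheet.to_csv(outdir / "sample_sheet.tsv", sep="\t", index=False)
    bmap.to_tsv(outdir / "barcode_map.tsv")
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    manifest = asdict(params)
    manifest["seed_used"] = params.seed if seed is None else seed
    manifest["timepoints"] = list(params.timepoints)
    pd.Series(manifest, dtype=object).to_json(outdir / "simulation_manifest.json", indent=2)
    return sheet


# ---------------------------------------------------------------------------
# colony plates

def simulate_colony_plates(
    n_strains: int,
    suppressor_fraction: float = 0.1,
    effect: float = 2.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
):
    """A control/treated plate pair with known suppressors.

    Control colony sizes are log-normal around 200 area units; treated
    sizes are the control sizes times ``effect`` for true suppressors (1
    otherwise) times log-normal noise of natural-log SD ``noise_sd``.
    """
    from repliid.sga import ColonyPlate

    if n_strains < 4:
        raise ValueError("need at least 4 strains")
    rng = np.random.default_rng(seed)
    strains = [f"str{i:04d}" for i in range(n_strains)]
    n_sup = int(round(suppressor_fraction * n_strains))
    is_sup = np.zeros(n_strains, dtype=bool)
    is_sup[rng.permutation(n_strains)[:n_sup]] = True

    ncol = int(math.ceil(math.sqrt(n_strains)))
    rows = [i // ncol + 1 for i in range(n_strains)]
    cols = [i % ncol + 1 for i in range(n_strains)]
    control_sizes = 200.0 * np.exp(rng.normal(0.0, 0.3, size=n_strains))
    mult = np.where(is_sup, effect, 1.0)
    noise = np.exp(rng.normal(0.0, noise_sd, size=n_strains)) if noise_sd > 0 else 1.0
    treated_sizes = control_sizes * mult * noise

    def plate(pid, cond, sizes):
        return ColonyPlate(
            pid,
            cond,
            pd.DataFrame({"row": rows, "column": cols, "strain_id": strains, "size": sizes}),
        )

    truth = pd.DataFrame({"strain_id": strains, "is_suppressor": is_sup})
    return plate("ctrl1", "control", control_sizes), plate("hu1", "treated", treated_sizes), truth


# ---------------------------------------------------------------------------
# recovery evaluation

@dataclass
class RecoveryReport:
    """Confusion matrix (true class x called class, with a ``not_scored``
    column for truth strains the pipeline filtered out) and the per-class
    sensitivity and precision derived from it."""

    confusion: pd.DataFrame
    sensitivity: dict
    precision: dict

    def __str__(self) -> str:
        lines = [self.confusion.to_string(), ""]
        for cls in self.confusion.index:
            s = self.sensitivity.get(cls, float("nan"))
            p = self.precision.get(cls, float("nan"))
            lines.append(f"{cls}: sensitivity={s:.3f} precision={p:.3f}")
        return "\n".join(lines)


def evaluate_recovery(
    score_table: pd.DataFrame, truth: pd.DataFrame, classes: tuple = None
) -> RecoveryReport:
    """Compare pipeline hit classes against simulated truth.

    ``score_table`` is indexed by gene with a ``hit_class`` column (the
    ``scores`` attribute of a screen result); ``truth`` is the generator's
    table.  Sensitivity for a class counts truth mutants of that class
    recovered with that call (strains the pipeline never scored count
    against it); precision counts correct calls among calls made.
    """
    mut_truth = truth[truth["strain_class"] == "mutant"].set_index("gene")
    unknown = set(score_table.index) - set(mut_truth.index)
    if unknown:
        raise ValueError(f"scored genes missing from truth, e.g. {sorted(unknown)[:3]}")
    true_classes = sorted(mut_truth["true_class"].unique())
    called_classes = classes or ("down_both", "up_both", "down_40_only", "down_80_only", "other")

    called = score_table["hit_class"]
    conf = pd.DataFrame(0, index=true_classes, columns=list(called_classes) + ["not_scored"])
    for gene, row in mut_truth.iterrows():
        t = row["true_class"]
        if gene in called.index:
            conf.loc[t, called.loc[gene]] += 1
        else:
            conf.loc[t, "not_scored"] += 1

    sensitivity, precision = {}, {}
    for cls in true_classes:
        total = int(conf.loc[cls].sum())
        sensitivity[cls] = conf.loc[cls, cls] / total if cls in conf.columns and total else float("nan")
    for cls in called_classes:
        n_called = int(conf[cls].sum())
        tp = int(conf.loc[cls, cls]) if cls in conf.index else 0
        precision[cls] = tp / n_called if n_called else float("nan")
    return RecoveryReport(confusion=conf, sensitivity=sensitivity, precision=precision)
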