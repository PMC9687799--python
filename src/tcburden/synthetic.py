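"""Synthetic expression datasets with known ground truth.

Every generator plants a hidden per-sample progression index x in [0, 1]
and builds log2-scale expression around it:

* a fraction of genes follow an "up" program (expression rises with x,
  emulating extracellular-matrix genes that climb with tumor progression),
* a fraction follow a "down" program (cell-cycle / translation / TCA-ETC /
  transcription-like genes that decline as the burden rises),
* the remaining background genes drift with x through a global gain term,
  which is what creates the per-sample burden gradient that TcB measures.

Programmed genes follow their program (baseline + sign*slope*x); background
genes carry the shared drift (baseline + global_gain*x). Gaussian noise is
added on the log2 scale — the pipeline consumes harmonized log-scale
matrices, so noise is modeled where the method operates. Hidden indices are
equally spaced rather than uniform-random so every TcB band is occupied
deterministically. All outputs are bit-reproducible given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import ExpressionMatrix, GeneSetCollection, SampleTable

#: Higher-order module labels for planted down-programs.
DOWN_MODULES = ("CELL_CYCLE_LIKE", "TRANSLATION_LIKE", "TCA_ETC_LIKE", "TRANSCRIPTION_LIKE")
UP_MODULE = "ECM_LIKE"

_CATEGORY_OF = {
    UP_MODULE: "ECM",
    "CELL_CYCLE_LIKE": "cell_cycle",
    "TRANSLATION_LIKE": "translation",
    "TCA_ETC_LIKE": "TCA_ETC",
    "TRANSCRIPTION_LIKE": "transcription",
}

#: "Strong" shift preset for the paired generator: a whole-transcriptome
#: additive log2 gain large enough to move a subject up one full TcB band
#: (see generate_paired_dataset).
STRONG_SHIFT_GAIN = 0.35

#: Activity levels paired subjects start from: centers chosen so that after
#: pooled min-max scaling they land in the low and mid TcB bands.
_PAIRED_LEVELS = (0.10, 0.45)


@dataclass
class SyntheticTruth:
    """Ground truth hidden from the pipeline.

    Attributes
    ----------
    samples
        ``sample_id, progression_index`` (plus ``subject_id, timepoint``
        for paired / longitudinal designs).
    genes
        ``gene_id, program`` (up/down/null), ``module`` (category or none).
    subjects
        Paired mode only: ``subject_id, shifter``.
    seed
        The seed the dataset was generated with.
    """

    samples: pd.DataFrame
    genes: pd.DataFrame
    subjects: pd.DataFrame | None
    seed: int


def _plant_genes(
    rng: np.random.Generator, n_genes: int, frac_up: float, frac_down: float
) -> tuple[list[str], np.ndarray, list[str], GeneSetCollection]:
    if frac_up < 0 or frac_down < 0 or frac_up + frac_down > 1:
        raise ConfigError("frac_up/frac_down must be >= 0 and sum to <= 1")
    n_up = int(round(frac_up * n_genes))
    n_down = int(round(frac_down * n_genes))
    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    perm = rng.permutation(n_genes)
    up_idx = perm[:n_up]
    down_idx = perm[n_up : n_up + n_down]
    sign = np.zeros(n_genes)
    sign[up_idx] = 1.0
    sign[down_idx] = -1.0
    module = ["none"] * n_genes
    for i in up_idx:
        module[i] = UP_MODULE
    for j, i in enumerate(down_idx):
        module[i] = DOWN_MODULES[j % len(DOWN_MODULES)]
    sets: dict[str, list[str]] = {}
    for name in (UP_MODULE, *DOWN_MODULES):
        members = [gene_ids[i] for i in range(n_genes) if module[i] == name]
        if members:
            sets[name] = members
    # background decoy set: should never enrich
    null_idx = [i for i in range(n_genes) if sign[i] == 0]
    if len(null_idx) >= 10:
        sets["HOUSEKEEPING_LIKE"] = [gene_ids[i] for i in null_idx[:10]]
    category_map = {name: _CATEGORY_OF.get(name, "housekeeping") for name in sets}
    return gene_ids, sign, module, GeneSetCollection(sets=sets, category_map=category_map)


def _expression(
    rng: np.random.Generator,
    baselines: np.ndarray,
    sign: np.ndarray,
    x: np.ndarray,
    slope: float,
    global_gain: float,
    noise_sd: float,
) -> np.ndarray:
    """log2 expression grid (genes x samples) for hidden indices ``x``."""
    programmed = sign != 0
    per_gene_slope = np.where(programmed, sign * slope, global_gain)
    clean = baselines[:, None] + per_gene_slope[:, None] * x[None, :]
    return clean + rng.normal(0.0, noise_sd, size=clean.shape)


def generate_progression_dataset(
    n_samples: int = 120,
    n_genes: int = 2000,
    frac_up: float = 0.05,
    frac_down: float = 0.05,
    baseline_mean: float = 8.0,
    baseline_sd: float = 1.0,
    slope: float = 2.0,
    noise_sd: float = 0.5,
    global_gain: float = 1.0,
    seed: int = 7,
) -> tuple[ExpressionMatrix, SyntheticTruth, GeneSetCollection]:
    """Cross-sectional cohort with a hidden progression axis.

    Sample ``i`` receives index ``x_i`` equally spaced on [0, 1]; gene
    values follow the module docstring's construction. Returns the log2
    matrix, the truth object and a GMT-style collection mapping the planted
    programs to higher-order categories.
    """
    if n_samples < 2 or n_genes < 2:
        raise ConfigError("need >= 2 samples and >= 2 genes")
    if noise_sd < 0:
        raise ConfigError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    gene_ids, sign, module, sets = _plant_genes(rng, n_genes, frac_up, frac_down)
    baselines = rng.normal(baseline_mean, baseline_sd, size=n_genes)
    x = np.linspace(0.0, 1.0, n_samples)
    sample_ids = [f"S{i:04d}" for i in range(n_samples)]
    values = _expression(rng, baselines, sign, x, slope, global_gain, noise_sd)
    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=gene_ids, columns=sample_ids), scale="log2"
    )
    truth = SyntheticTruth(
        samples=pd.DataFrame({"sample_id": sample_ids, "progression_index": x}),
        genes=pd.DataFrame(
            {
                "gene_id": gene_ids,
                "program": np.where(sign > 0, "up", np.where(sign < 0, "down", "null")),
                "module": module,
            }
        ),
        subjects=None,
        seed=seed,
    )
    return matrix, truth, sets


def generate_paired_dataset(
    n_subjects: int = 41,
    frac_shifters: float = 24 / 41,
    shift_gain: float = STRONG_SHIFT_GAIN,
    n_genes: int = 2000,
    frac_up: float = 0.05,
    frac_down: float = 0.05,
    baseline_mean: float = 8.0,
    baseline_sd: float = 1.0,
    slope: float = 2.0,
    noise_sd: float = 0.5,
    global_gain: float = 1.0,
    seed: int = 7,
) -> tuple[ExpressionMatrix, SampleTable, SyntheticTruth, GeneSetCollection]:
    """Paired initial/relapse cohort with designated shifters.

    Each subject contributes one sample per timepoint. Subjects start
    alternately at a low- or mid-band activity level; a seeded random
    subset (``frac_shifters``) are shifters whose second timepoint receives
    an additive global log2 gain of ``shift_gain`` on every background gene
    plus the matching program progression on planted genes. Non-shifters
    change by noise only. The default cohort mirrors a relapse study of 41
    subjects of whom 24 shift.
    """
    if n_subjects < 4:
        raise ConfigError("paired design needs >= 4 subjects to occupy the TcB bands")
    if not (0.0 < frac_shifters < 1.0):
        raise ConfigError("frac_shifters must be in (0, 1)")
    if global_gain <= 0:
        raise ConfigError("paired design requires global_gain > 0")
    rng = np.random.default_rng(seed)
    gene_ids, sign, module, sets = _plant_genes(rng, n_genes, frac_up, frac_down)
    baselines = rng.normal(baseline_mean, baseline_sd, size=n_genes)

    subject_ids = [f"SUBJ{i:03d}" for i in range(n_subjects)]
    n_shift = int(round(frac_shifters * n_subjects))
    n_shift = min(max(n_shift, 1), n_subjects - 1)
    shifter = np.zeros(n_subjects, dtype=bool)
    shifter[rng.permutation(n_subjects)[:n_shift]] = True
    # alternate starting bands so both bands hold shifters and non-shifters
    a1 = np.array([_PAIRED_LEVELS[i % 2] for i in range(n_subjects)])
    delta = shift_gain / global_gain  # index step equivalent to the global gain
    a2 = a1 + np.where(shifter, delta, 0.0)

    x = np.concatenate([a1, a2])
    sample_ids = [f"{s}_initial" for s in subject_ids] + [f"{s}_relapse" for s in subject_ids]
    values = _expression(rng, baselines, sign, x, slope, global_gain, noise_sd)
    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=gene_ids, columns=sample_ids), scale="log2"
    )
    meta = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "subject_id": subject_ids * 2,
            "timepoint": ["initial"] * n_subjects + ["relapse"] * n_subjects,
        }
    )
    metadata = SampleTable(table=meta, timepoint_order=["initial", "relapse"])
    truth = SyntheticTruth(
        samples=pd.DataFrame(
            {
                "sample_id": sample_ids,
                "subject_id": subject_ids * 2,
                "timepoint": meta["timepoint"],
                "progression_index": x,
            }
        ),
        genes=pd.DataFrame(
            {
                "gene_id": gene_ids,
                "program": np.where(sign > 0, "up", np.where(sign < 0, "down", "null")),
                "module": module,
            }
        ),
        subjects=pd.DataFrame({"subject_id": subject_ids, "shifter": shifter}),
        seed=seed,
    )
    return matrix, metadata, truth, sets


def generate_longitudinal_reversal(
    n_subjects: int = 6,
    n_timepoints: int = 3,
    reversal_strength: float = 0.25,
    n_genes: int = 2000,
    frac_up: float = 0.05,
    frac_down: float = 0.05,
    baseline_mean: float = 8.0,
    baseline_sd: float = 1.0,
    slope: float = 2.0,
    noise_sd: float = 0.5,
    global_gain: float = 1.0,
    seed: int = 7,
    timepoint_labels: list[str] | None = None,
) -> tuple[ExpressionMatrix, SampleTable, SyntheticTruth, GeneSetCollection]:
    """Multi-timepoint treatment-reversal course.

    Subjects start at staggered high progression indices; each interval
    lowers the index by ``reversal_strength``, so global expression and
    up-program genes decay while down-program genes recover symmetrically —
    the mirror image of the progression plant. The default (6 subjects x 3
    timepoints) mirrors a treatment study sampled at days 0, 7 and 21.
    """
    if n_timepoints < 2:
        raise ConfigError("longitudinal design needs >= 2 timepoints")
    if n_subjects < 1:
        raise ConfigError("need >= 1 subject")
    rng = np.random.default_rng(seed)
    gene_ids, sign, module, sets = _plant_genes(rng, n_genes, frac_up, frac_down)
    baselines = rng.normal(baseline_mean, baseline_sd, size=n_genes)
    if timepoint_labels is None:
        timepoint_labels = (
            ["day0", "day7", "day21"] if n_timepoints == 3 else [f"t{i}" for i in range(n_timepoints)]
        )
    if len(timepoint_labels) != n_timepoints:
        raise ConfigError("timepoint_labels length must equal n_timepoints")
    subject_ids = [f"SUBJ{i:03d}" for i in range(n_subjects)]
    x0 = np.linspace(0.6, 1.0, n_subjects) if n_subjects > 1 else np.array([0.8])

    sample_ids, subj_col, tp_col, x_list = [], [], [], []
    for t, label in enumerate(timepoint_labels):
        for j, subj in enumerate(subject_ids):
            sample_ids.append(f"{subj}_{label}")
            subj_col.append(subj)
            tp_col.append(label)
            x_list.append(x0[j] - reversal_strength * t)
    x = np.array(x_list)
    values = _expression(rng, baselines, sign, x, slope, global_gain, noise_sd)
    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=gene_ids, columns=sample_ids), scale="log2"
    )
    meta = pd.DataFrame({"sample_id": sample_ids, "subject_id": subj_col, "timepoint": tp_col})
    metadata = SampleTable(table=meta, timepoint_order=list(timepoint_labels))
    truth = SyntheticTruth(
        samples=pd.DataFrame(
            {
                "sample_id": sample_ids,
                "subject_id": subj_col,
                "timepoint": tp_col,
                "progression_index": x,
            }
        ),
        genes=pd.DataFrame(
            {
                "gene_id": gene_ids,
                "program": np.where(sign > 0, "up", np.where(sign < 0, "down", "null")),
                "module": module,
            }
        ),
        subjects=None,
        seed=seed,
    )
    return matrix, metadata, truth, sets
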