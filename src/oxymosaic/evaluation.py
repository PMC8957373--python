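"""Model evaluation: weighted RMS error, leave-one-subject-out protocol,
hidden-layer sweep, phase statistics and Bland-Altman agreement.

The performance metric is the weighted RMS error

    E_rms,W = sqrt( sum_i w_i (y_i - yhat_i)^2 / sum_i w_i )

where w_i is the inverse-frequency weight of sample i's 10% SO2 bin, so
every occupied part of the 0-100% range counts equally regardless of how
unevenly the occlusion protocol populates it.

Leave-one-subject-out (LOSO): each subject in turn is excluded entirely;
a network is trained on the pooled spectra of the remaining subjects
(with its internal random 70/15/15 train/val/test split) and scored on
the untouched subject.  Method agreement with the reference is assessed
per protocol phase (baseline, end of occlusion, early after release)
with Bland-Altman bias and 1.96-SD limits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ann import ShallowANNRegressor
from .sampling import SpectrumSet
from .weighting import WeightVector, compute_weight_vector, lookup_weights

__all__ = [
    "erms_w", "BlandAltman", "bland_altman", "interval_summary",
    "LOSOResult", "loso_run", "node_sweep", "summarize_sweep",
    "repetition_stability", "ablation_venous_only", "subject_series",
    "cohort_phase_table", "summarize_phases", "cohort_bland_altman",
]

logger = logging.getLogger(__name__)

SWEEP_SIZES = (1, 2, 3, 4, 5, 7, 10, 15, 20)


def erms_w(y_true: np.ndarray, y_pred: np.ndarray,
           weights: np.ndarray) -> float:
    """Weighted RMS error (%) between target and predicted SO2."""
    y_true = np.asarray(y_true, dtype=np.float64)
    y_pred = np.asarray(y_pred, dtype=np.float64)
    w = np.asarray(weights, dtype=np.float64)
    if not (y_true.shape == y_pred.shape == w.shape):
        raise ValueError("y_true, y_pred and weights must have equal shapes")
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    total = w.sum()
    if total == 0:
        raise ValueError("weights must not be all zero")
    return float(np.sqrt(np.sum(w * (y_true - y_pred) ** 2) / total))


# ---------------------------------------------------------------------------
# Bland-Altman and protocol phases
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BlandAltman:
    """Agreement statistics for paired per-subject values.

    ``differences`` are method_a - method_b (default convention:
    network minus reference); ``upper``/``lower`` are bias +/- 1.96
    sample standard deviations.
    """

    bias: float
    sd: float
    upper: float
    lower: float
    differences: np.ndarray = field(repr=False, default=None)


def bland_altman(method_a: np.ndarray, method_b: np.ndarray) -> BlandAltman:
    a = np.asarray(method_a, dtype=np.float64)
    b = np.asarray(method_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D arrays")
    if a.size < 2:
        raise ValueError("Bland-Altman needs at least 2 pairs")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltman(bias=bias, sd=sd, upper=bias + 1.96 * sd,
                       lower=bias - 1.96 * sd, differences=d)


def _window_mean(times: np.ndarray, values: np.ndarray,
                 window: tuple[float, float]) -> float:
    sel = (times >= window[0]) & (times <= window[1])
    if not sel.any():
        return np.nan
    return float(np.mean(values[sel]))


def _nearest_resample(times: np.ndarray, values: np.ndarray,
                      at: np.ndarray) -> np.ndarray:
    idx = np.clip(np.searchsorted(times, at), 1, len(times) - 1)
    left_closer = (at - times[idx - 1]) <= (times[idx] - at)
    return values[np.where(left_closer, idx - 1, idx)]


def interval_summary(times_method: np.ndarray, values_method: np.ndarray,
                     ref_times: np.ndarray, ref_values: np.ndarray,
                     protocol) -> pd.DataFrame:
    """Per-phase values for one subject's method and reference series.

    Baseline and end-of-occlusion values are window means of each series
    at its native rate.  The release value captures the distinct
    reperfusion peak: the peak is located on the reference series inside
    the release window, and both methods report the median of the nine
    reference-rate samples centered on that peak index (truncated at the
    window edges), the method series being resampled at those times by
    nearest neighbor.
    """
    rows = []
    for phase, window in (("baseline", protocol.baseline_window),
                          ("end_occlusion", protocol.end_occlusion_window)):
        rows.append({"phase": phase,
                     "method": _window_mean(times_method, values_method, window),
                     "reference": _window_mean(ref_times, ref_values, window)})

    window = protocol.release_window
    sel = np.flatnonzero((ref_times >= window[0]) & (ref_times <= window[1]))
    if sel.size == 0:
        rows.append({"phase": "release", "method": np.nan, "reference": np.nan})
    else:
        peak = sel[np.argmax(ref_values[sel])]
        lo, hi = max(peak - 4, sel[0]), min(peak + 4, sel[-1])
        if hi - lo < 8:
            logger.warning("release peak window truncated to %d samples",
                           hi - lo + 1)
        pick = np.arange(lo, hi + 1)
        rows.append({
            "phase": "release",
            "method": float(np.median(_nearest_resample(
                times_method, values_method, ref_times[pick]))),
            "reference": float(np.median(ref_values[pick])),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# LOSO harness
# ---------------------------------------------------------------------------

def _derived_seed(*keys) -> int:
    import zlib
    ints = tuple(k if isinstance(k, (int, np.integer))
                 else zlib.crc32(str(k).encode()) for k in keys)
    return int(np.random.SeedSequence(ints).generate_state(1)[0] % 2 ** 31)


@dataclass
class LOSOResult:
    """Per-fold errors and the fitted per-fold models."""

    folds: pd.DataFrame
    models: dict[str, ShallowANNRegressor]
    weight_vector: WeightVector

    @property
    def mean_erms_eval(self) -> float:
        return float(self.folds["erms_eval"].mean())


def _fit_fold(pool: SpectrumSet, weight_vector: WeightVector, n_hidden: int,
              init_seed: int, split_seed: int, weighted: bool,
              estimator_kwargs: dict) -> ShallowANNRegressor:
    sw = lookup_weights(weight_vector, pool.y) if weighted else None
    model = ShallowANNRegressor(n_hidden=n_hidden, random_state=init_seed,
                                split_random_state=split_seed,
                                **estimator_kwargs)
    return model.fit(pool.X, pool.y, sample_weight=sw)


def _fold_errors(model: ShallowANNRegressor, pool: SpectrumSet,
                 eval_set: SpectrumSet,
                 weight_vector: WeightVector) -> dict[str, float]:
    """E_rms,W on the pool's train/test splits and on the left-out data.

    The metric weights always come from the weight vector (the training
    ``weighted`` flag changes the loss, not the metric).
    """
    out = {}
    pool_pred = model.predict(pool.X)
    pool_w = lookup_weights(weight_vector, pool.y)
    for name in ("train", "test"):
        idx = model.split_indices_[name]
        out[f"erms_{name}"] = erms_w(pool.y[idx], pool_pred[idx], pool_w[idx])
    ew = lookup_weights(weight_vector, eval_set.y)
    out["erms_eval"] = erms_w(eval_set.y, model.predict(eval_set.X), ew)
    return out


def loso_run(spectra: SpectrumSet, weight_vector: WeightVector | None = None,
             n_hidden: int = 3, seed: int = 0, weighted: bool = True,
             weight_scope: str = "global",
             train_filter=None, eval_filter=None,
             estimator_kwargs: dict | None = None) -> LOSOResult:
    """Leave-one-subject-out training and evaluation.

    ``weight_scope='global'`` computes the weight vector once from every
    subject's targets, mirroring the original protocol (the left-out
    subject's targets inform the bin weights; switch to ``'train-only'``
    for a leakage-free variant).  ``train_filter`` / ``eval_filter``
    select rows (boolean function of the spectra table), e.g. to train
    on venous-only data or evaluate on arterial-only data.
    """
    if weight_scope not in ("global", "train-only"):
        raise ValueError("weight_scope must be 'global' or 'train-only'")
    estimator_kwargs = estimator_kwargs or {}
    frame = spectra.frame
    subject_ids = sorted(frame["subject_id"].unique())
    if len(subject_ids) < 3:
        raise ValueError("LOSO needs at least 3 subjects")
    if weight_vector is None and weight_scope == "global":
        weight_vector = compute_weight_vector(spectra.y)

    rows, models = [], {}
    metric_w = weight_vector
    for i, sid in enumerate(subject_ids):
        is_left_out = frame["subject_id"] == sid
        pool = spectra.subset(~is_left_out)
        if train_filter is not None:
            pool = pool.subset(train_filter(pool.frame))
        eval_set = spectra.subset(is_left_out)
        if eval_filter is not None:
            eval_set = eval_set.subset(eval_filter(eval_set.frame))
        if len(eval_set) == 0:
            logger.warning("subject %s has no evaluation data; fold skipped", sid)
            continue
        w_fold = (weight_vector if weight_scope == "global"
                  else compute_weight_vector(pool.y))
        model = _fit_fold(pool, w_fold, n_hidden,
                          init_seed=_derived_seed(seed, i, 0),
                          split_seed=_derived_seed(seed, i, "split"),
                          weighted=weighted, estimator_kwargs=estimator_kwargs)
        metric_w = weight_vector if weight_vector is not None else w_fold
        errs = _fold_errors(model, pool, eval_set, metric_w)
        rows.append({"subject_id": sid, "n_pool": len(pool),
                     "n_eval": len(eval_set), **errs,
                     "stop_reason": model.stop_reason_,
                     "n_epochs": model.n_iter_})
        models[sid] = model
    return LOSOResult(folds=pd.DataFrame(rows), models=models,
                      weight_vector=metric_w)


def node_sweep(spectra: SpectrumSet, sizes=SWEEP_SIZES, reps: int = 10,
               weight_vector: WeightVector | None = None, seed: int = 0,
               weighted: bool = True, subjects: list[str] | None = None,
               estimator_kwargs: dict | None = None) -> pd.DataFrame:
    """Hidden-layer size sweep with re-initialized repetitions.

    For every LOSO fold, every size in ``sizes`` is trained ``reps``
    times from fresh initializations (same pool and split within a
    fold), giving ``len(sizes) * reps`` networks per fold.  Returns a
    tidy table (subject, n_hidden, rep, test/evaluation errors).
    """
    estimator_kwargs = estimator_kwargs or {}
    frame = spectra.frame
    subject_ids = subjects or sorted(frame["subject_id"].unique())
    if weight_vector is None:
        weight_vector = compute_weight_vector(spectra.y)
    rows = []
    for i, sid in enumerate(subject_ids):
        is_left_out = frame["subject_id"] == sid
        pool = spectra.subset(~is_left_out)
        eval_set = spectra.subset(is_left_out)
        split_seed = _derived_seed(seed, i, "split")
        for h in sizes:
            for rep in range(reps):
                model = _fit_fold(pool, weight_vector, h,
                                  init_seed=_derived_seed(seed, i, h, rep),
                                  split_seed=split_seed, weighted=weighted,
                                  estimator_kwargs=estimator_kwargs)
                errs = _fold_errors(model, pool, eval_set, weight_vector)
                rows.append({"subject_id": sid, "n_hidden": h, "rep": rep, **errs})
    return pd.DataFrame(rows)


def summarize_sweep(sweep: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD of the errors per hidden-layer size (across folds x reps)."""
    return (sweep.groupby("n_hidden")[["erms_test", "erms_eval"]]
            .agg(["mean", "std"]))


def repetition_stability(spectra: SpectrumSet, subject_id: str,
                         weight_vector: WeightVector | None = None,
                         n_hidden: int = 3, reps: int = 10, seed: int = 0,
                         weighted: bool = True,
                         estimator_kwargs: dict | None = None) -> np.ndarray:
    """Evaluation E_rms,W of ``reps`` re-initialized trainings on one fold
    (identical pool and split; only the starting weights differ)."""
    sweep = node_sweep(spectra, sizes=(n_hidden,), reps=reps,
                       weight_vector=weight_vector, seed=seed,
                       weighted=weighted, subjects=[subject_id],
                       estimator_kwargs=estimator_kwargs)
    return sweep["erms_eval"].to_numpy()


def ablation_venous_only(spectra: SpectrumSet,
                         weight_vector: WeightVector | None = None,
                         n_hidden: int = 3, seed: int = 0,
                         estimator_kwargs: dict | None = None) -> LOSOResult:
    """Train on venous-occlusion spectra only (same global weight vector),
    evaluate each left-out subject on its arterial data."""
    if weight_vector is None:
        weight_vector = compute_weight_vector(spectra.y)
    return loso_run(
        spectra, weight_vector=weight_vector, n_hidden=n_hidden, seed=seed,
        train_filter=lambda f: (f["provocation"] == "venous").to_numpy(),
        eval_filter=lambda f: (f["provocation"] == "arterial").to_numpy(),
        estimator_kwargs=estimator_kwargs)


# ---------------------------------------------------------------------------
# Cohort-level time series, phase tables, agreement
# ---------------------------------------------------------------------------

def subject_series(model: ShallowANNRegressor, spectra: SpectrumSet,
                   subject_id: str,
                   provocation: str = "arterial") -> tuple[np.ndarray, np.ndarray]:
    """Per-cube network SO2 series: mean prediction over each cube's
    sampled pixels, ordered by cube timestamp."""
    f = spectra.frame
    sel = (f["subject_id"] == subject_id) & (f["provocation"] == provocation)
    sub = spectra.subset(sel.to_numpy())
    pred = pd.Series(model.predict(sub.X),
                     index=sub.frame["timestamp_s"].to_numpy())
    series = pred.groupby(level=0).mean()
    return series.index.to_numpy(), series.to_numpy()


def cohort_phase_table(models: dict[str, ShallowANNRegressor],
                       spectra: SpectrumSet, traces: dict, protocol,
                       provocation: str = "arterial") -> pd.DataFrame:
    """Per-subject phase values (network vs reference) for one provocation."""
    rows = []
    for sid, model in models.items():
        t, v = subject_series(model, spectra, sid, provocation)
        trace = traces[(sid, provocation)]
        summary = interval_summary(t, v, trace.times_s, trace.so2, protocol)
        summary.insert(0, "subject_id", sid)
        rows.append(summary)
    return pd.concat(rows, ignore_index=True)


def summarize_phases(phase_table: pd.DataFrame) -> pd.DataFrame:
    """Cohort phase summary: mean (SD) [max min] per phase and method."""
    long = phase_table.melt(id_vars=["subject_id", "phase"],
                            value_vars=["method", "reference"],
                            var_name="source", value_name="so2")
    return (long.groupby(["phase", "source"])["so2"]
            .agg(["mean", "std", "max", "min"]).reset_index())


def cohort_bland_altman(phase_table: pd.DataFrame) -> dict[str, BlandAltman]:
    """Bland-Altman (network minus reference) per protocol phase."""
    out = {}
    for phase, grp in phase_table.groupby("phase"):
        out[phase] = bland_altman(grp["method"].to_numpy(),
                                  grp["reference"].to_numpy())
    return out
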