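"""Two-stage arc-ROI optimization and cross-validated TSB estimation.

Stage 1 repeatedly draws TSB-stratified train/test resamples, optimizes the
placement (radius, width, angular centre) of all 9 arc ROIs by bounded
generalized pattern search against the test-set sum of squared GLM
prediction errors, and aggregates the per-resample optima by parameter-wise
medians.  Stage 2 freezes the median ROIs and cross-validates the gamma GLM
over many stratified 5-patient test splits, reporting each patient's median
predicted TSB across the iterations in which they were held out.

Stratification follows the clinical bin edges: 4 bins (0-5, 5.01-10,
10.01-15, 15.01-25 mg/dL) with 2 train per bin (8 train) and 2/2/2/1 test
(7 test) in stage 1; 5 bins (0-3.5, 3.51-6.5, 6.51-10, 10.01-15, 15.01-25)
with 1 test per bin (5 test, remainder trains) in stage 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InvalidParameterError, StratificationError
from .glm import GammaGLMRegressor
from .roi import ROISet, arc_roi_mask, extract_features
from .exceptions import BiliphoneError

#: clinical TSB bin edges, mg/dL
STAGE1_EDGES = (0.0, 5.0, 10.0, 15.0, 25.0)
STAGE2_EDGES = (0.0, 3.5, 6.5, 10.0, 15.0, 25.0)


@dataclass(frozen=True)
class StrataSpec:
    """TSB stratification: bin edges plus per-bin train/test counts.

    ``n_train_per_bin`` of None means "everything not in the test set".
    ``n_test_per_bin`` may be a single count or one count per bin.
    """

    bin_edges: tuple[float, ...]
    n_train_per_bin: int | None
    n_test_per_bin: int | tuple[int, ...]

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        if edges.size < 2 or np.any(np.diff(edges) <= 0):
            raise InvalidParameterError("bin_edges must be strictly increasing")
        n_bins = edges.size - 1
        if isinstance(self.n_test_per_bin, tuple) and len(self.n_test_per_bin) != n_bins:
            raise InvalidParameterError("n_test_per_bin length must match bin count")

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges) - 1

    def test_counts(self) -> tuple[int, ...]:
        if isinstance(self.n_test_per_bin, tuple):
            return self.n_test_per_bin
        return (int(self.n_test_per_bin),) * self.n_bins


def stage1_spec() -> StrataSpec:
    return StrataSpec(bin_edges=STAGE1_EDGES, n_train_per_bin=2, n_test_per_bin=(2, 2, 2, 1))


def stage2_spec() -> StrataSpec:
    return StrataSpec(bin_edges=STAGE2_EDGES, n_train_per_bin=None, n_test_per_bin=1)


def _bin_members(patients: pd.DataFrame, edges: tuple[float, ...]) -> list[np.ndarray]:
    tsb = patients["tsb_mg_dl"].to_numpy(dtype=float)
    ids = patients["patient_id"].to_numpy()
    members = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (tsb > lo) & (tsb <= hi)
        members.append(ids[sel])
    return members


def stratified_split(
    patients: pd.DataFrame, spec: StrataSpec, seed: int | np.random.Generator
) -> tuple[list, list]:
    """Draw disjoint (train_ids, test_ids) stratified by TSB bin.

    Sampling is without replacement within each bin; deterministic under a
    fixed seed.  Raises :class:`StratificationError` naming any bin that
    cannot supply the requested counts.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    members = _bin_members(patients, spec.bin_edges)
    test_counts = spec.test_counts()
    train_ids: list = []
    test_ids: list = []
    for b, ids in enumerate(members):
        lo, hi = spec.bin_edges[b], spec.bin_edges[b + 1]
        n_train = spec.n_train_per_bin if spec.n_train_per_bin is not None else 0
        need = n_train + test_counts[b]
        if len(ids) < need:
            raise StratificationError(
                f"bin ({lo}, {hi}] mg/dL holds {len(ids)} patients, needs {need}"
            )
        perm = rng.permutation(len(ids))
        train_ids.extend(ids[perm[:n_train]])
        test_ids.extend(ids[perm[n_train:n_train + test_counts[b]]])
    if spec.n_train_per_bin is None:
        test_set = set(test_ids)
        train_ids = [i for i in patients["patient_id"] if i not in test_set]
    return train_ids, test_ids


# ---------------------------------------------------------------------------
# Feature cache and objective
# ---------------------------------------------------------------------------


class CohortFeatures:
    """Fast ROI-mean evaluation over a cohort of same-shape calibrated images.

    Precomputes the polar pixel grid and flattens the per-patient channel
    images so that an arbitrary :class:`ROISet` can be evaluated with a few
    vectorized boolean operations per ROI.
    """

    def __init__(self, patients: pd.DataFrame, images: dict):
        self.patients = patients.reset_index(drop=True)
        self.ids = list(self.patients["patient_id"])
        self.tsb = self.patients["tsb_mg_dl"].to_numpy(dtype=float)
        self._index = {pid: i for i, pid in enumerate(self.ids)}
        first = images[self.ids[0]]
        self.shape = first.rgb.shape[:2]
        self.mm_per_px = first.mm_per_px
        self.origin = first.origin
        xx, yy = first.pixel_coordinates()
        self.rr = np.hypot(xx, yy).ravel()
        self.ang = np.degrees(np.arctan2(yy, xx)).ravel()
        n = len(self.ids)
        npx = self.rr.size
        self.channels = {
            c: np.zeros((n, npx)) for c in ("red", "green", "blue")
        }
        self.valid = np.zeros((n, npx), dtype=bool)
        for pid in self.ids:
            img = images[pid]
            if img.rgb.shape[:2] != self.shape:
                raise InvalidParameterError("cohort images must share a common shape")
            i = self._index[pid]
            for c in ("red", "green", "blue"):
                self.channels[c][i] = img.channel(c).ravel()
            self.valid[i] = img.saturation_mask.ravel()

    def rows(self, ids) -> np.ndarray:
        return np.array([self._index[i] for i in ids], dtype=int)

    def features(self, rois: ROISet, ids) -> np.ndarray | None:
        """(len(ids), n_rois) ROI-mean matrix, or None if any ROI is degenerate."""
        rows = self.rows(ids)
        out = np.empty((rows.size, len(rois)))
        for j, roi in enumerate(rois.rois):
            dang = np.abs((self.ang - roi.theta + 180.0) % 360.0 - 180.0)
            mask = (
                (self.rr >= roi.radius - roi.width / 2)
                & (self.rr <= roi.radius + roi.width / 2)
                & (dang <= roi.span / 2)
            )
            if not mask.any():
                return None
            ch = self.channels[roi.channel][rows][:, mask]
            val = self.valid[rows][:, mask]
            counts = val.sum(axis=1)
            if np.any(counts == 0):
                return None
            out[:, j] = np.where(val, ch, 0.0).sum(axis=1) / counts
        return out


def roi_objective(
    rois: ROISet,
    cohort: CohortFeatures,
    train_ids,
    eval_ids,
    link: str = "log",
) -> float:
    """Sum of squared prediction errors (mg/dL^2) of the GLM on the eval set.

    Fits on the training resample, evaluates on the held-out resample.
    Infeasible or degenerate ROI sets (arc outside the FOV, fully saturated,
    non-finite fit) return +inf — barrier semantics for the pattern search.
    """
    lo, hi = rois.vector_bounds()
    vec = rois.to_vector()
    if np.any(vec < lo) or np.any(vec > hi):
        return np.inf
    for roi in rois.rois:
        if roi.radius - roi.width / 2 <= 0:
            return np.inf
    x_train = cohort.features(rois, train_ids)
    x_eval = cohort.features(rois, eval_ids)
    if x_train is None or x_eval is None:
        return np.inf
    y_train = cohort.tsb[cohort.rows(train_ids)]
    y_eval = cohort.tsb[cohort.rows(eval_ids)]
    try:
        model = GammaGLMRegressor(link=link, strict=False).fit(x_train, y_train)
        pred = model.predict(x_eval)
    except BiliphoneError:
        return np.inf
    if not np.all(np.isfinite(pred)):
        return np.inf
    return float(np.sum((pred - y_eval) ** 2))


# ---------------------------------------------------------------------------
# Generalized pattern search
# ---------------------------------------------------------------------------


@dataclass
class PatternSearchResult:
    best: np.ndarray
    objective: float
    trace: list[float]
    n_evaluations: int


def pattern_search(
    objective,
    x0: np.ndarray,
    lower: np.ndarray,
    upper: np.ndarray,
    budget: int = 500,
    initial_mesh: float = 0.1,
    mesh_tolerance: float = 1e-3,
) -> PatternSearchResult:
    """Bounded generalized pattern search over a box.

    Polls each coordinate in turn at +/- one mesh step (scaled per-parameter
    by the box width), accepts the first improvement, doubles the mesh on a
    successful poll cycle and halves it on failure; iterates are clipped to
    the box.  Stops when the evaluation ``budget`` is exhausted or the mesh
    falls below ``mesh_tolerance``.  The accepted-step objective trace is
    non-increasing and the returned objective never exceeds the initial one.
    """
    if budget < 1:
        raise InvalidParameterError("budget must be >= 1")
    x = np.clip(np.asarray(x0, dtype=float), lower, upper)
    scale = np.asarray(upper, float) - np.asarray(lower, float)
    scale[scale <= 0] = 1.0
    f = objective(x)
    if not np.isfinite(f):
        raise InvalidParameterError("pattern search requires a feasible start")
    evals = 1
    mesh = initial_mesh
    trace = [f]
    while evals < budget and mesh >= mesh_tolerance:
        improved = False
        for i in range(x.size):
            for sign in (+1.0, -1.0):
                if evals >= budget:
                    break
                cand = x.copy()
                cand[i] = np.clip(cand[i] + sign * mesh * scale[i], lower[i], upper[i])
                if cand[i] == x[i]:
                    continue
                fc = objective(cand)
                evals += 1
                if fc < f:
                    x, f = cand, fc
                    trace.append(f)
                    improved = True
                    break
            if improved or evals >= budget:
                break
        mesh = mesh * 2.0 if improved else mesh * 0.5
        mesh = min(mesh, 1.0)
    return PatternSearchResult(best=x, objective=f, trace=trace, n_evaluations=evals)


# ---------------------------------------------------------------------------
# Stage 1: resampled ROI optimization
# ---------------------------------------------------------------------------


def _lower_median(values: np.ndarray) -> float:
    """Median with the lower-median convention for even counts."""
    v = np.sort(np.asarray(values, dtype=float))
    return float(v[(v.size - 1) // 2])


@dataclass
class Stage1Result:
    median_rois: ROISet
    table: pd.DataFrame  # one row per (resample, roi): optimized parameters
    seed: int
    n_resamples: int


def optimize_rois_stage1(
    cohort: CohortFeatures,
    init: ROISet,
    spec: StrataSpec | None = None,
    n_resamples: int = 3000,
    budget: int = 500,
    seed: int = 0,
    link: str = "log",
) -> Stage1Result:
    """Resampled pattern-search optimization of ROI placement.

    For each resample: draw a stratified train/test split, minimize the
    test-set SSE over all ROI parameters by pattern search, store the
    optimum.  The output ROISet takes the parameter-wise median over
    resamples for each ROI slot (lower-median convention for even counts).
    """
    spec = spec or stage1_spec()
    lo, hi = init.vector_bounds()
    rng = np.random.default_rng(seed)
    rows = []
    vectors = np.empty((n_resamples, init.to_vector().size))
    for r in range(n_resamples):
        train_ids, test_ids = stratified_split(cohort.patients, spec, rng)

        def objective(vec):
            try:
                rois = init.with_vector(vec)
            except BiliphoneError:
                return np.inf  # infeasible arc parameters: barrier
            return roi_objective(rois, cohort, train_ids, test_ids, link=link)

        result = pattern_search(objective, init.to_vector(), lo, hi, budget=budget)
        vectors[r] = result.best
        for j, roi in enumerate(init.with_vector(result.best).rois):
            rows.append(
                {
                    "resample": r,
                    "roi": j,
                    "channel": roi.channel,
                    "radius_mm": roi.radius,
                    "width_mm": roi.width,
                    "theta_deg": roi.theta,
                    "sse": result.objective,
                }
            )
    median_vec = np.array([_lower_median(vectors[:, j]) for j in range(vectors.shape[1])])
    return Stage1Result(
        median_rois=init.with_vector(median_vec),
        table=pd.DataFrame(rows),
        seed=seed,
        n_resamples=n_resamples,
    )


# ---------------------------------------------------------------------------
# Stage 2: stratified cross-validation
# ---------------------------------------------------------------------------


@dataclass
class CVResult:
    """Per-patient predicted-TSB distributions across CV iterations."""

    per_patient_predictions: dict
    median_prediction: dict
    n_iterations: int
    seed: int
    coverage_warning: list = field(default_factory=list)

    def to_frame(self, patients: pd.DataFrame) -> pd.DataFrame:
        recs = []
        for _, row in patients.iterrows():
            pid = row["patient_id"]
            preds = self.per_patient_predictions.get(pid, [])
            recs.append(
                {
                    "patient_id": pid,
                    "tsb_mg_dl": row["tsb_mg_dl"],
                    "median_prediction": self.median_prediction.get(pid, np.nan),
                    "n_test_appearances": len(preds),
                    "skin_group": row.get("skin_group", ""),
                }
            )
        return pd.DataFrame(recs)


def cross_validate_stage2(
    cohort: CohortFeatures,
    final_rois: ROISet,
    spec: StrataSpec | None = None,
    n_iterations: int = 10000,
    seed: int = 0,
    link: str = "log",
) -> CVResult:
    """Stratified cross-validation of the gamma GLM at fixed ROI positions.

    Per iteration: hold out one patient per stage-2 TSB bin, fit on the
    remainder, record the held-out predictions.  Patients never sampled
    into a test set are listed in ``coverage_warning``.
    """
    spec = spec or stage2_spec()
    feats = cohort.features(final_rois, cohort.ids)
    if feats is None:
        raise InvalidParameterError("final ROI set is degenerate on this cohort")
    rng = np.random.default_rng(seed)
    preds: dict = {pid: [] for pid in cohort.ids}
    for _ in range(n_iterations):
        train_ids, test_ids = stratified_split(cohort.patients, spec, rng)
        tr = cohort.rows(train_ids)
        te = cohort.rows(test_ids)
        try:
            model = GammaGLMRegressor(link=link, strict=False).fit(
                feats[tr], cohort.tsb[tr]
            )
        except BiliphoneError:
            continue  # discard degenerate resample
        p = model.predict(feats[te])
        for pid, value in zip(test_ids, p):
            preds[pid].append(float(value))
    missing = [pid for pid, v in preds.items() if not v]
    if missing:
        import warnings

        warnings.warn(
            f"{len(missing)} patients never appeared in a test set: {missing}",
            stacklevel=2,
        )
    medians = {pid: float(np.median(v)) for pid, v in preds.items() if v}
    return CVResult(
        per_patient_predictions=preds,
        median_prediction=medians,
        n_iterations=n_iterations,
        seed=seed,
        coverage_warning=missing,
    )
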