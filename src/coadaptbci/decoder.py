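"""Decoding frontend: shrinkage-CSP per band, log-bandpower features, sLDA.

The online unit bandpass-filters the EEG into 15 mu/beta bands, learns per
band a shrinkage-regularized common-spatial-patterns (CSP) projection from a
3-s imagery epoch, keeps the 3 most hand-discriminative and 3 most
feet-discriminative projections, and computes the log band power of each
projection over a trailing 1-s window — 15 x 6 = 90 features — which a
shrinkage-regularized linear discriminant (sLDA) maps to a scalar score
(positive = feet imagery). Estimators follow scikit-learn conventions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg as spla
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .data_model import FEET, HAND, Trial, TrialTiming
from .preprocess import FilterBank, apply_filterbank, build_filterbank

N_SELECTED = 6          # CSP projections kept per band (first 3 + last 3)
POWER_FLOOR = 1e-10     # μV², floors degenerate windows before the log
STREAM_RATE_HZ = 16     # classifier output rate


def _trial_covariances(X: np.ndarray) -> np.ndarray:
    """Per-trial empirical channel covariances, mean removed, divisor n."""
    Xc = X - X.mean(axis=-1, keepdims=True)
    return np.einsum("tcn,tdn->tcd", Xc, Xc) / X.shape[-1]


def analytic_shrinkage(covs: np.ndarray) -> float:
    """Ledoit–Wolf-style intensity for an average of per-trial covariances.

    Treats each trial's covariance matrix as one i.i.d. observation of the
    class covariance and shrinks their mean toward the scaled identity
    ``(tr(C)/d) I``: the intensity is the ratio of the estimator's sampling
    variance to its squared distance from the target, clipped to [0, 1].
    """
    covs = np.asarray(covs, dtype=float)
    t, d = covs.shape[0], covs.shape[1]
    cbar = covs.mean(axis=0)
    target = (np.trace(cbar) / d) * np.eye(d)
    dist2 = float(np.sum((cbar - target) ** 2))
    if t < 2 or dist2 <= 0.0:
        return 1.0 if dist2 <= 0.0 else 0.0
    var = float(np.sum((covs - cbar) ** 2)) / (t * (t - 1))
    return float(np.clip(var / dist2, 0.0, 1.0))


def _shrink(cov: np.ndarray, gamma: float) -> np.ndarray:
    d = cov.shape[0]
    return (1.0 - gamma) * cov + gamma * (np.trace(cov) / d) * np.eye(d)


class ShrinkageCSP(TransformerMixin, BaseEstimator):
    """Two-class CSP with per-class covariance shrinkage (one band).

    Fitting whitens the summed shrunk class covariances and eigendecomposes
    the whitened hand-class covariance; filter columns are ordered by
    descending eigenvalue, so leading columns maximize hand-class variance
    and trailing columns maximize feet-class variance. ``transform`` keeps
    the first and last ``n_select/2`` projections.

    Parameters
    ----------
    shrinkage : float or None
        Fixed intensity in [0, 1]; ``None`` uses :func:`analytic_shrinkage`
        per class.
    n_select : int
        Number of retained projections (split evenly between extremes).
    """

    def __init__(self, shrinkage: float | None = None, n_select: int = N_SELECTED):
        self.shrinkage = shrinkage
        self.n_select = n_select

    def fit(self, X, y):
        """Fit from band-filtered epochs, shape (n_trials, n_ch, n_samples)."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        return self.fit_from_covariances(_trial_covariances(X), y)

    def fit_from_covariances(self, covs, y):
        """Fit from per-trial epoch covariances, shape (n_trials, n_ch, n_ch)."""
        covs = np.asarray(covs, dtype=float)
        y = np.asarray(y)
        classes = np.unique(y)
        if set(classes.tolist()) != {HAND, FEET}:
            raise ValueError(f"need both classes {{hand={HAND}, feet={FEET}}}, got {classes}")
        d = covs.shape[1]
        if self.n_select > d:
            raise ValueError(f"cannot select {self.n_select} of {d} projections")

        per_class = {}
        self.shrinkage_ = {}
        for k in (HAND, FEET):
            ck = covs[y == k]
            if len(ck) < 2:
                raise ValueError(f"need >= 2 trials for class {k}")
            g = self.shrinkage if self.shrinkage is not None else analytic_shrinkage(ck)
            self.shrinkage_[k] = float(g)
            per_class[k] = _shrink(ck.mean(axis=0), g)

        composite = per_class[HAND] + per_class[FEET]
        evals, evecs = np.linalg.eigh(composite)
        if self.shrinkage == 0.0 and evals.min() <= 1e-12 * evals.max():
            raise np.linalg.LinAlgError(
                "rank-deficient composite covariance; use nonzero shrinkage")
        whitener = evecs @ np.diag(evals ** -0.5) @ evecs.T
        s_hand = whitener @ per_class[HAND] @ whitener.T
        s_hand = (s_hand + s_hand.T) / 2.0
        lam, rot = np.linalg.eigh(s_hand)
        order = np.argsort(lam)[::-1]                  # descending hand eigenvalue
        self.eigenvalues_ = lam[order]
        self.filters_ = whitener.T @ rot[:, order]     # columns are spatial filters
        self.patterns_ = np.linalg.inv(self.filters_.T)
        h = self.n_select // 2
        self.selected_ = np.r_[np.arange(h), np.arange(d - (self.n_select - h), d)]
        return self

    def transform(self, X):
        """Project epochs onto the selected CSP filters.

        Returns shape (n_trials, n_select, n_samples).
        """
        check_is_fitted(self, "filters_")
        X = np.asarray(X, dtype=float)
        w = self.filters_[:, self.selected_]
        return np.einsum("cs,tcn->tsn", w, X)


class CSPBank(BaseEstimator):
    """One :class:`ShrinkageCSP` per filterbank band."""

    def __init__(self, shrinkage: float | None = None, n_select: int = N_SELECTED):
        self.shrinkage = shrinkage
        self.n_select = n_select

    def fit(self, X, y):
        """X: band-filtered epochs, shape (n_trials, n_bands, n_ch, n_samples)."""
        X = np.asarray(X, dtype=float)
        covs = np.stack([_trial_covariances(X[:, b]) for b in range(X.shape[1])],
                        axis=1)
        return self.fit_from_covariances(covs, y)

    def fit_from_covariances(self, covs, y):
        """covs: shape (n_trials, n_bands, n_ch, n_ch)."""
        covs = np.asarray(covs, dtype=float)
        self.csps_ = []
        for b in range(covs.shape[1]):
            csp = ShrinkageCSP(shrinkage=self.shrinkage, n_select=self.n_select)
            csp.fit_from_covariances(covs[:, b], y)
            self.csps_.append(csp)
        self.n_bands_ = covs.shape[1]
        return self

    @property
    def n_features_(self) -> int:
        check_is_fitted(self, "csps_")
        return self.n_bands_ * self.n_select

    def selected_filters(self) -> np.ndarray:
        """Stacked selected filters, shape (n_bands, n_ch, n_select)."""
        check_is_fitted(self, "csps_")
        return np.stack([c.filters_[:, c.selected_] for c in self.csps_])


class ShrinkageLDA(ClassifierMixin, BaseEstimator):
    """Linear discriminant with identity-target covariance shrinkage.

    The pooled within-class covariance S is replaced by
    ``(1 - γ) S + γ (tr S / d) I`` with γ picked by the Ledoit–Wolf analytic
    formula unless fixed, which keeps the discriminant well defined even
    when features outnumber trials. Score convention: ``w·x + b`` with feet
    positive; a score of exactly 0 predicts hand.
    """

    def __init__(self, shrinkage: float | None = None):
        self.shrinkage = shrinkage

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_samples, n_features)")
        classes = np.unique(y)
        if set(classes.tolist()) != {HAND, FEET}:
            raise ValueError(f"need both classes {{hand={HAND}, feet={FEET}}}, got {classes}")
        for k in (HAND, FEET):
            if np.sum(y == k) < 2:
                raise ValueError(f"class {k} has fewer than 2 samples")
        n, d = X.shape
        mu = {k: X[y == k].mean(axis=0) for k in (HAND, FEET)}
        centered = X.copy()
        for k in (HAND, FEET):
            centered[y == k] -= mu[k]
        pooled = centered.T @ centered / (n - 2)
        if self.shrinkage is None:
            from sklearn.covariance import ledoit_wolf_shrinkage
            gamma = float(ledoit_wolf_shrinkage(centered, assume_centered=True))
        else:
            gamma = float(self.shrinkage)
        sigma = _shrink(pooled, gamma)
        delta = mu[FEET] - mu[HAND]
        w = spla.solve(sigma, delta, assume_a="pos")
        self.classes_ = np.array([HAND, FEET])
        self.gamma_ = gamma
        self.means_ = np.stack([mu[HAND], mu[FEET]])
        self.covariance_ = sigma
        self.coef_ = w
        self.intercept_ = float(-w @ (mu[HAND] + mu[FEET]) / 2.0)
        # per-class linear discriminant parts for softmax probabilities
        a = spla.solve(sigma, self.means_.T, assume_a="pos").T     # (2, d)
        self._class_w = a
        self._class_b = -0.5 * np.einsum("kd,kd->k", a, self.means_)
        return self

    def decision_function(self, X):
        check_is_fitted(self, "coef_")
        return np.asarray(X, dtype=float) @ self.coef_ + self.intercept_

    def class_scores(self, X):
        """Per-class linear discriminant values z = (g_hand, g_feet).

        Their difference equals :meth:`decision_function`; the softmax of z
        gives the class probabilities.
        """
        check_is_fitted(self, "coef_")
        return np.asarray(X, dtype=float) @ self._class_w.T + self._class_b

    def predict(self, X):
        s = self.decision_function(X)
        return np.where(s > 0, FEET, HAND)

    def predict_proba(self, X):
        from .retraining import softmax
        return softmax(self.class_scores(X))


# ---------------------------------------------------------------------------
# feature extraction
# ---------------------------------------------------------------------------

def _window_bounds(at_time_s: float, fs: float, n_samples: int) -> tuple[int, int]:
    stop = int(round(at_time_s * fs))
    start = stop - int(round(fs))
    if start < 0 or stop > n_samples:
        raise ValueError(
            f"1-s window [{at_time_s - 1}, {at_time_s}) s outside available data")
    return start, stop


def extract_features(filtered: np.ndarray, csp: CSPBank, at_time_s: float,
                     fs: float) -> np.ndarray:
    """Log band power of each selected CSP projection over [t-1, t).

    Parameters
    ----------
    filtered : ndarray, shape (n_bands, n_ch, n_samples)
        Causally band-filtered trial (output of ``apply_filterbank``).

    Returns the band-major feature vector of length n_bands x n_select
    (90 for the default frontend).
    """
    filtered = np.asarray(filtered, dtype=float)
    start, stop = _window_bounds(at_time_s, fs, filtered.shape[-1])
    w = csp.selected_filters()                      # (B, C, S)
    seg = filtered[:, :, start:stop]                # (B, C, N)
    proj = np.einsum("bcs,bcn->bsn", w, seg)
    var = proj.var(axis=-1)
    return np.log(np.maximum(var, POWER_FLOOR)).ravel()


def features_from_moments(second_moment: np.ndarray, mean: np.ndarray,
                          csp: CSPBank) -> np.ndarray:
    """Features from cached per-band window moments (fast retraining path).

    ``second_moment``: (n_bands, n_ch, n_ch) = X Xᵀ / n over the window;
    ``mean``: (n_bands, n_ch). For a projection w the window variance is
    wᵀSw - (wᵀm)², identical to the direct computation.
    """
    w = csp.selected_filters()                                     # (B, C, S)
    var = (np.einsum("bcs,bcd,bds->bs", w, second_moment, w)
           - np.einsum("bcs,bc->bs", w, mean) ** 2)
    return np.log(np.maximum(var, POWER_FLOOR)).ravel()


def window_moments(filtered: np.ndarray, at_time_s: float, fs: float
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Cacheable (second moment, mean) of the 1-s window ending at ``at_time_s``."""
    start, stop = _window_bounds(at_time_s, fs, filtered.shape[-1])
    seg = filtered[:, :, start:stop]
    s = np.einsum("bcn,bdn->bcd", seg, seg) / seg.shape[-1]
    return s, seg.mean(axis=-1)


# ---------------------------------------------------------------------------
# the full decoder
# ---------------------------------------------------------------------------

@dataclass
class DecoderModel:
    """A fitted frontend snapshot: filterbank + CSP bank + sLDA + provenance."""

    fb: FilterBank
    csp: CSPBank
    slda: ShrinkageLDA
    version: int = 0
    n_trials_used: int = 0
    label_source: str = "true"          # "true" | "artificial" | "mixed"


@dataclass
class ScoreSeries:
    """Per-output-sample stream-classifier results for one trial."""

    times_s: np.ndarray                 # window end times, trial-start referenced
    scores: np.ndarray                  # scalar LDA scores (feet positive)
    class_scores: np.ndarray            # (n_out, 2) per-class discriminants
    predictions: np.ndarray             # class ids
    model_version: int = 0


def classify_stream(trial, model: DecoderModel, rate_hz: int = STREAM_RATE_HZ,
                    filtered: np.ndarray | None = None) -> ScoreSeries:
    """Score a trial at ``rate_hz`` outputs per second, causally.

    One score is emitted for every window end time ``t = 1, 1 + 1/rate, …``
    once a full 1-s window is available; nothing is emitted before 1 s.
    ``rate_hz`` must divide the sampling rate.
    """
    fs = model.fb.fs
    if int(fs) % int(rate_hz) != 0:
        raise ValueError(f"rate {rate_hz} Hz does not divide fs {fs} Hz")
    stride = int(fs) // int(rate_hz)
    if filtered is None:
        data = trial.data if isinstance(trial, Trial) else np.asarray(trial)
        filtered = apply_filterbank(model.fb, data)
    n = filtered.shape[-1]
    w = model.csp.selected_filters()                       # (B, C, S)
    proj = np.einsum("bcs,bcn->bsn", w, filtered)          # (B, S, N)
    flat = proj.reshape(-1, n)                             # (B*S, N) band-major

    win = int(round(fs))
    ends = np.arange(win, n + 1, stride)
    c1 = np.cumsum(flat, axis=1)
    c2 = np.cumsum(flat ** 2, axis=1)
    z = np.zeros((flat.shape[0], 1))
    c1 = np.hstack([z, c1])
    c2 = np.hstack([z, c2])
    s1 = c1[:, ends] - c1[:, ends - win]
    s2 = c2[:, ends] - c2[:, ends - win]
    var = s2 / win - (s1 / win) ** 2
    feats = np.log(np.maximum(var, POWER_FLOOR)).T         # (n_out, B*S)

    zscores = model.slda.class_scores(feats)
    scores = zscores[:, 1] - zscores[:, 0]
    preds = np.where(scores > 0, FEET, HAND)
    return ScoreSeries(times_s=ends / fs, scores=scores, class_scores=zscores,
                       predictions=preds, model_version=model.version)


class MotorImageryDecoder(ClassifierMixin, BaseEstimator):
    """End-to-end trial classifier: filterbank → CSP bank → 90 features → sLDA.

    ``fit`` takes raw trials (n_trials, n_ch, n_samples) with class labels;
    CSP is learned on the 3-s imagery epoch and the sLDA on the single 1-s
    log-bandpower feature vector ending at the configured feature time.
    """

    def __init__(self, bands=None, filter_order: int = 8, fs: float = 256.0,
                 csp_shrinkage: float | None = None,
                 lda_shrinkage: float | None = None,
                 timing: TrialTiming | None = None):
        self.bands = bands
        self.filter_order = filter_order
        self.fs = fs
        self.csp_shrinkage = csp_shrinkage
        self.lda_shrinkage = lda_shrinkage
        self.timing = timing

    def _timing(self) -> TrialTiming:
        return self.timing or TrialTiming()

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        timing = self._timing()
        fb = build_filterbank(self.bands, self.filter_order, self.fs)
        lo = int(round(timing.csp_epoch[0] * self.fs))
        hi = int(round(timing.csp_epoch[1] * self.fs))
        filtered = np.stack([apply_filterbank(fb, t) for t in X])  # (T, B, C, N)
        csp = CSPBank(shrinkage=self.csp_shrinkage).fit(filtered[..., lo:hi], y)
        feats = np.stack([
            extract_features(f, csp, timing.lda_feature_time_s, self.fs)
            for f in filtered
        ])
        slda = ShrinkageLDA(shrinkage=self.lda_shrinkage).fit(feats, y)
        self.model_ = DecoderModel(fb=fb, csp=csp, slda=slda,
                                   n_trials_used=len(y))
        self.classes_ = np.array([HAND, FEET])
        return self

    def _features(self, X) -> np.ndarray:
        timing = self._timing()
        return np.stack([
            extract_features(apply_filterbank(self.model_.fb, t),
                             self.model_.csp, timing.lda_feature_time_s, self.fs)
            for t in np.asarray(X, dtype=float)
        ])

    def decision_function(self, X):
        check_is_fitted(self, "model_")
        return self.model_.slda.decision_function(self._features(X))

    def predict(self, X):
        s = self.decision_function(X)
        return np.where(s > 0, FEET, HAND)

    def predict_proba(self, X):
        check_is_fitted(self, "model_")
        return self.model_.slda.predict_proba(self._features(X))


# ---------------------------------------------------------------------------
# thin functional wrappers and serialization
# ---------------------------------------------------------------------------

def fit_csp_bank(trials, labels, fb: FilterBank,
                 timing: TrialTiming | None = None,
                 shrinkage: float | None = None) -> CSPBank:
    """Fit the per-band CSP models from raw trials on the 3-s imagery epoch."""
    timing = timing or TrialTiming()
    lo = int(round(timing.csp_epoch[0] * fb.fs))
    hi = int(round(timing.csp_epoch[1] * fb.fs))
    data = np.stack([t.data if isinstance(t, Trial) else np.asarray(t)
                     for t in trials])
    filtered = np.stack([apply_filterbank(fb, d) for d in data])
    return CSPBank(shrinkage=shrinkage).fit(filtered[..., lo:hi], np.asarray(labels))


def fit_slda(features, labels, shrinkage: float | None = None) -> ShrinkageLDA:
    return ShrinkageLDA(shrinkage=shrinkage).fit(np.asarray(features),
                                                 np.asarray(labels))


def save_model(path, model: DecoderModel) -> None:
    """Serialize a fitted decoder to HDF5; reload reproduces identical scores."""
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["version"] = model.version
        f.attrs["n_trials_used"] = model.n_trials_used
        f.attrs["label_source"] = model.label_source
        f.attrs["fs"] = model.fb.fs
        f.attrs["filter_order"] = model.fb.order
        f.create_dataset("bands", data=np.asarray(model.fb.bands))
        g = f.create_group("csp")
        g.attrs["n_select"] = model.csp.csps_[0].n_select
        g.create_dataset("filters", data=np.stack([c.filters_ for c in model.csp.csps_]))
        g.create_dataset("eigenvalues", data=np.stack([c.eigenvalues_ for c in model.csp.csps_]))
        g.create_dataset("selected", data=np.stack([c.selected_ for c in model.csp.csps_]))
        l = f.create_group("slda")
        l.attrs["gamma"] = model.slda.gamma_
        l.create_dataset("coef", data=model.slda.coef_)
        l.create_dataset("intercept", data=model.slda.intercept_)
        l.create_dataset("means", data=model.slda.means_)
        l.create_dataset("covariance", data=model.slda.covariance_)
        l.create_dataset("class_w", data=model.slda._class_w)
        l.create_dataset("class_b", data=model.slda._class_b)


def load_model(path) -> DecoderModel:
    import h5py

    with h5py.File(path, "r") as f:
        fb = build_filterbank([tuple(b) for b in f["bands"][()]],
                              int(f.attrs["filter_order"]), float(f.attrs["fs"]))
        g = f["csp"]
        n_select = int(g.attrs["n_select"])
        bank = CSPBank(n_select=n_select)
        bank.csps_ = []
        filters = g["filters"][()]
        evals = g["eigenvalues"][()]
        selected = g["selected"][()]
        for b in range(filters.shape[0]):
            csp = ShrinkageCSP(n_select=n_select)
            csp.filters_ = filters[b]
            csp.eigenvalues_ = evals[b]
            csp.selected_ = selected[b]
            csp.patterns_ = np.linalg.inv(csp.filters_.T)
            bank.csps_.append(csp)
        bank.n_bands_ = filters.shape[0]
        l = f["slda"]
        slda = ShrinkageLDA()
        slda.classes_ = np.array([HAND, FEET])
        slda.gamma_ = float(l.attrs["gamma"])
        slda.coef_ = l["coef"][()]
        slda.intercept_ = float(l["intercept"][()])
        slda.means_ = l["means"][()]
        slda.covariance_ = l["covariance"][()]
        slda._class_w = l["class_w"][()]
        slda._class_b = l["class_b"][()]
        return DecoderModel(fb=fb, csp=bank, slda=slda,
                            version=int(f.attrs["version"]),
                            n_trials_used=int(f.attrs["n_trials_used"]),
                            label_source=str(f.attrs["label_source"]))


__all__ = [
    "N_SELECTED", "POWER_FLOOR", "STREAM_RATE_HZ",
    "analytic_shrinkage", "ShrinkageCSP", "CSPBank", "ShrinkageLDA",
    "extract_features", "features_from_moments", "window_moments",
    "DecoderModel", "ScoreSeries", "classify_stream", "MotorImageryDecoder",
    "fit_csp_bank", "fit_slda", "save_model", "load_model",
]
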