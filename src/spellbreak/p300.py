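"""The P300 speller victim model.

Pipeline (the classical Riemannian approach that won the 2015 Kaggle BCI
challenge): 0-600 ms epochs locked to each intensification -> 16 xDAWN
spatial filters (8 per class) -> "super-trial" covariance of the filtered
epoch stacked with the filtered class-mean evoked templates -> shrinkage
-> tangent-space projection at the geometric mean of the training
covariances -> class-weighted logistic regression on tangent vectors ->
probability voting over repeats to pick the target row and column.

Every stage is differentiable in the input epoch (for finite inputs the
shrinkage keeps all covariances positive-definite), and
:func:`loss_gradient` returns the exact gradient of the cross-entropy
loss with respect to the epoch samples, which the attack module uses to
build its perturbation template.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg
from sklearn.linear_model import LogisticRegression

from . import riemann
from .chars import p300_char_at
from .synth import P300Session

__all__ = [
    "Epoch",
    "XdawnFilters",
    "P300ModelConfig",
    "P300VictimModel",
    "extract_epochs",
    "epoch_length",
    "fit_xdawn",
    "supertrial_covariance",
    "train",
    "predict_proba",
    "loss_gradient",
    "decode_character",
    "decode_session",
]

EPOCH_SECONDS = 0.600


def epoch_length(fs: float) -> int:
    return int(round(EPOCH_SECONDS * fs))


@dataclass
class Epoch:
    data: np.ndarray  # (n_channels, L)
    label: int  # 1 target, 0 nontarget
    stimulus_id: int
    trial_index: int
    repeat_index: int


def extract_epochs(session: P300Session) -> list[Epoch]:
    """One 0-600 ms epoch per intensification event.

    Label 1 iff the stimulus id matches the trial's target row or column.
    """
    L = epoch_length(session.fs)
    n = session.signal.shape[1]
    targets = {t.trial_index: (t.target_row, 6 + t.target_col) for t in session.trials}
    out: list[Epoch] = []
    for e in session.events:
        if e.onset_sample + L > n:
            raise ValueError(
                f"epoch window for event at sample {e.onset_sample} "
                "extends past the end of the recording"
            )
        label = int(e.stimulus_id in targets[e.trial_index])
        out.append(
            Epoch(
                session.signal[:, e.onset_sample : e.onset_sample + L],
                label,
                e.stimulus_id,
                e.trial_index,
                e.repeat_index,
            )
        )
    return out


def _epoch_array(epochs: list[Epoch]) -> tuple[np.ndarray, np.ndarray]:
    data = np.stack([e.data for e in epochs])
    labels = np.array([e.label for e in epochs])
    return data, labels


# ---------------------------------------------------------------------------
# xDAWN


@dataclass
class XdawnFilters:
    """Spatial filters enhancing the evoked response of each class.

    ``w_target`` and ``w_nontarget`` are (n_channels, 8) with unit-norm
    columns; ``evoked_target`` / ``evoked_nontarget`` are the filtered
    class-mean responses (8, L) used as templates in the super-trial.
    """

    w_target: np.ndarray
    w_nontarget: np.ndarray
    evoked_target: np.ndarray
    evoked_nontarget: np.ndarray

    @property
    def stacked(self) -> np.ndarray:
        """All 16 filters, target first: (n_channels, 16)."""
        return np.hstack([self.w_target, self.w_nontarget])


def _xdawn_class_filters(
    evoked: np.ndarray, total_cov: np.ndarray, n_components: int
) -> np.ndarray:
    """Generalized eigenproblem: evoked power against total signal power."""
    sig_cov = evoked @ evoked.T / evoked.shape[1]
    try:
        w, v = scipy.linalg.eigh(sig_cov, total_cov)
    except scipy.linalg.LinAlgError:
        warnings.warn("singular total covariance in xDAWN; applying shrinkage")
        m = total_cov.shape[0]
        total_cov = 0.99 * total_cov + 0.01 * np.trace(total_cov) / m * np.eye(m)
        w, v = scipy.linalg.eigh(sig_cov, total_cov)
    order = np.argsort(w)[::-1][:n_components]
    filters = v[:, order]
    return filters / np.linalg.norm(filters, axis=0, keepdims=True)


def fit_xdawn(
    data: np.ndarray, labels: np.ndarray, n_components: int = 8
) -> XdawnFilters:
    """Fit 2 x ``n_components`` xDAWN filters from epochs (n, C, L).

    Per class the filters maximize the ratio of synchronized-average
    (evoked) power to total signal power; deterministic given the input.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("both target and nontarget epochs are required")
    total_cov = np.einsum("ncl,nkl->ck", data, data) / (data.shape[0] * data.shape[2])
    ev1 = data[labels == 1].mean(axis=0)
    ev0 = data[labels == 0].mean(axis=0)
    w1 = _xdawn_class_filters(ev1, total_cov, n_components)
    w0 = _xdawn_class_filters(ev0, total_cov, n_components)
    return XdawnFilters(w1, w0, w1.T @ ev1, w0.T @ ev0)


# ---------------------------------------------------------------------------
# super-trial covariances


def _supertrial_stack(data: np.ndarray, filters: XdawnFilters) -> np.ndarray:
    """Stack [filtered target template; filtered nontarget template;
    16-filter-projected epoch] -> (n, 32, L).  Batched."""
    single = data.ndim == 2
    if single:
        data = data[None]
    proj = np.einsum("cf,ncl->nfl", filters.stacked, data)
    n = data.shape[0]
    t1 = np.broadcast_to(filters.evoked_target, (n,) + filters.evoked_target.shape)
    t0 = np.broadcast_to(filters.evoked_nontarget, (n,) + filters.evoked_nontarget.shape)
    z = np.concatenate([t1, t0, proj], axis=1)
    return z[0] if single else z


def _cov_of_stack(z: np.ndarray, shrinkage: float) -> np.ndarray:
    """Row-centered sample covariance with trace-preserving shrinkage."""
    zc = z - z.mean(axis=-1, keepdims=True)
    m, L = z.shape[-2], z.shape[-1]
    c = zc @ np.swapaxes(zc, -1, -2) / (L - 1)
    tr = np.trace(c, axis1=-2, axis2=-1)
    eye = np.eye(m)
    return (1.0 - shrinkage) * c + shrinkage * (tr / m)[..., None, None] * eye


def supertrial_covariance(
    data: np.ndarray, filters: XdawnFilters, shrinkage: float = 0.01
) -> np.ndarray:
    """Shrunk covariance of the template-augmented epoch (32 x 32).

    Accepts a single epoch (C, L) or a batch (n, C, L).
    """
    if not np.all(np.isfinite(data)):
        raise ValueError("epoch data contain non-finite values")
    return _cov_of_stack(_supertrial_stack(data, filters), shrinkage)


# ---------------------------------------------------------------------------
# the trained model


@dataclass(frozen=True)
class P300ModelConfig:
    n_xdawn: int = 8
    shrinkage: float = 0.01
    mean_tol: float = 1e-8
    mean_max_iter: int = 50
    # inverse L2 regularization strength (sklearn convention): 1.0 puts the
    # penalty at order 1/n relative to the per-sample loss -- weak
    logreg_c: float = 1.0


@dataclass
class P300VictimModel:
    config: P300ModelConfig
    filters: XdawnFilters
    c_ref: np.ndarray  # (32, 32) geometric mean of training covariances
    coef: np.ndarray  # (m(m+1)/2,) logistic weights on tangent vectors
    intercept: float
    class_weights: dict[int, float]
    fs: float

    @property
    def n_channels(self) -> int:
        return self.filters.w_target.shape[0]

    @property
    def epoch_len(self) -> int:
        return epoch_length(self.fs)

    def _irt(self) -> np.ndarray:
        return riemann.sym_powm(self.c_ref, -0.5)

    def features(self, data: np.ndarray) -> np.ndarray:
        """Tangent-space feature vector(s) for epoch data (.., C, L)."""
        cov = supertrial_covariance(data, self.filters, self.config.shrinkage)
        return riemann.tangent_map(cov, self.c_ref)

    def decision_function(self, data: np.ndarray) -> np.ndarray:
        return self.features(data) @ self.coef + self.intercept

    def predict_proba(self, data: np.ndarray) -> np.ndarray:
        """Probability that the epoch(s) contain a P300 response."""
        if data.shape[-2:] != (self.n_channels, self.epoch_len):
            raise ValueError(
                f"expected epoch shape ({self.n_channels}, {self.epoch_len}), "
                f"got {data.shape[-2:]}"
            )
        return 1.0 / (1.0 + np.exp(-self.decision_function(data)))


def train(config: P300ModelConfig, session: P300Session) -> P300VictimModel:
    """Fit the victim model on a training session.

    Class weights are inversely proportional to class counts (10 nontarget
    vs 2 target intensifications per repeat gives a 5:1 ratio).
    """
    epochs = extract_epochs(session)
    data, labels = _epoch_array(epochs)
    if len(np.unique(labels)) < 2:
        raise ValueError("training session contains a single class")
    filters = fit_xdawn(data, labels, config.n_xdawn)
    covs = supertrial_covariance(data, filters, config.shrinkage)
    c_ref = riemann.geometric_mean(covs, config.mean_tol, config.mean_max_iter)
    feats = riemann.tangent_map(covs, c_ref)

    n = len(labels)
    n1 = int(labels.sum())
    class_weights = {0: n / (2.0 * (n - n1)), 1: n / (2.0 * n1)}
    clf = LogisticRegression(
        C=config.logreg_c, class_weight=class_weights, solver="lbfgs",
        max_iter=2000, tol=1e-10,
    )
    clf.fit(feats, labels)
    return P300VictimModel(
        config=config,
        filters=filters,
        c_ref=c_ref,
        coef=clf.coef_[0].copy(),
        intercept=float(clf.intercept_[0]),
        class_weights=class_weights,
        fs=session.fs,
    )


def predict_proba(model: P300VictimModel, data: np.ndarray) -> np.ndarray:
    return model.predict_proba(data)


# ---------------------------------------------------------------------------
# gradients


def loss_gradient(
    model: P300VictimModel, data: np.ndarray, y: np.ndarray | int
) -> np.ndarray:
    """Gradient of the cross-entropy loss w.r.t. the epoch samples.

    ``J = -y log p - (1-y) log(1-p)`` with ``p = predict_proba(data)``.
    Accepts a single epoch (C, L) or a batch (n, C, L); the gradient has
    the same shape as ``data``.  The chain runs backwards through the
    logistic map, the tangent-space vectorization, the matrix logarithm
    (Daleckii-Krein adjoint), the shrinkage, the centered covariance and
    the fixed spatial projection.
    """
    single = data.ndim == 2
    if single:
        data = data[None]
    y_arr = np.broadcast_to(np.asarray(y, float), (data.shape[0],))

    gamma = model.config.shrinkage
    m = model.c_ref.shape[0]
    L = data.shape[-1]
    irt = model._irt()

    z = _supertrial_stack(data, model.filters)  # (n, 32, L)
    zc = z - z.mean(axis=-1, keepdims=True)
    c = zc @ np.swapaxes(zc, -1, -2) / (L - 1)
    tr = np.trace(c, axis1=-2, axis2=-1)
    cs = (1.0 - gamma) * c + gamma * (tr / m)[..., None, None] * np.eye(m)
    mat = irt @ cs @ irt
    v = riemann.vec_upper(riemann.logm_spd(mat))
    p = 1.0 / (1.0 + np.exp(-(v @ model.coef + model.intercept)))

    # backward pass
    g_v = (p - y_arr)[:, None] * model.coef[None, :]
    g_log = riemann.unvec_upper(g_v, m)  # gradient w.r.t. the log-matrix
    g_mat = riemann.logm_frechet_adjoint(mat, g_log)
    g_cs = irt @ g_mat @ irt
    g_c = (1.0 - gamma) * g_cs + (gamma / m) * np.trace(
        g_cs, axis1=-2, axis2=-1
    )[..., None, None] * np.eye(m)
    g_c = 0.5 * (g_c + np.swapaxes(g_c, -1, -2))
    g_zc = 2.0 / (L - 1) * g_c @ zc
    g_z = g_zc - g_zc.mean(axis=-1, keepdims=True)
    # only the projected-epoch rows (16:32) depend on the input
    g_x = np.einsum("cf,nfl->ncl", model.filters.stacked, g_z[:, 2 * model.config.n_xdawn :])
    return g_x[0] if single else g_x


# ---------------------------------------------------------------------------
# character decoding


def score_table(
    model: P300VictimModel, session: P300Session, trial_index: int, n_repeats: int
) -> dict[int, float]:
    """Summed target probabilities per stimulus id over the first repeats."""
    evs = session.trial_events(trial_index, n_repeats)
    L = model.epoch_len
    data = np.stack([session.signal[:, e.onset_sample : e.onset_sample + L] for e in evs])
    probs = model.predict_proba(data)
    table = {sid: 0.0 for sid in range(1, 13)}
    for e, pr in zip(evs, probs):
        table[e.stimulus_id] += float(pr)
    return table


def decode_character(
    model: P300VictimModel, session: P300Session, trial_index: int, n_repeats: int
) -> str:
    """Probability-sum voting over repeats; ties go to the lowest id."""
    table = score_table(model, session, trial_index, n_repeats)
    rows = np.array([table[sid] for sid in range(1, 7)])
    cols = np.array([table[sid] for sid in range(7, 13)])
    return p300_char_at(int(np.argmax(rows)) + 1, int(np.argmax(cols)) + 1)


def decode_session(
    model: P300VictimModel, session: P300Session, n_repeats: int
) -> list[str]:
    return [
        decode_character(model, session, t.trial_index, n_repeats)
        for t in session.trials
    ]
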