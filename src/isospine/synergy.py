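"""Muscle synergy extraction and antagonist co-contraction coupling.

The normalized envelope matrix M (channels x time) is factorized by
non-negative matrix factorization, M = W H + E, where the columns of W
are spatial synergy vectors and the rows of H their temporal activations.
The model order S is the smallest one whose variance accounted for,
VAF(S) = 1 - ||M - WH||_F^2 / ||M||_F^2, exceeds a threshold (80% by
default).  From the flexor- and extensor-dominated columns of W, group
coupling ratios quantify antagonist co-contraction and drive the
synergy-coupled activation of the antagonist muscle group during forward
simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import NMF

from .emg import EnvelopeMatrix

__all__ = [
    "SynergySet",
    "SynergyCoupling",
    "SynergyExtractor",
    "extract_synergies",
    "coupling_from_W",
    "antagonist_activation",
]

A_FLOOR = 0.02  # controller activation floor, also the co-contraction clip floor


@dataclass
class SynergySet:
    """NMF factorization with VAF bookkeeping.

    W is channels x S with each column max-normalized to 1 (the scale is
    folded into H); vaf_by_order[k] is the best-of-restarts VAF at order
    k+1.
    """

    W: np.ndarray
    H: np.ndarray
    S: int
    vaf_by_order: list[float]
    residual_norm: float
    labels: list[str] = field(default_factory=list)

    @property
    def vaf(self) -> float:
        return self.vaf_by_order[self.S - 1]


@dataclass(frozen=True)
class SynergyCoupling:
    """Group-aggregated synergy weights.

    w_ext_flx: mean flexor-channel weight in the extensor-dominated vector
    (and analogously for the other three).  The off/on ratios
    w_ext_flx/w_flx_flx and w_flx_ext/w_ext_ext set the antagonist
    activation during extension and flexion respectively.
    """

    w_ext_flx: float
    w_flx_flx: float
    w_flx_ext: float
    w_ext_ext: float

    def __post_init__(self) -> None:
        for v in (self.w_ext_flx, self.w_flx_flx, self.w_flx_ext, self.w_ext_ext):
            if not (0.0 <= v <= 1.0 + 1e-12):
                raise ValueError("coupling weights must lie in [0, 1]")
        if self.w_flx_flx <= 0 or self.w_ext_ext <= 0:
            raise ValueError("dominant-group coupling weights must be positive")

    @property
    def ratio_flexor_during_ext(self) -> float:
        return self.w_ext_flx / self.w_flx_flx

    @property
    def ratio_extensor_during_flx(self) -> float:
        return self.w_flx_ext / self.w_ext_ext


class SynergyExtractor(TransformerMixin, BaseEstimator):
    """NMF synergy extraction with VAF-based order selection.

    sklearn conventions: X is (n_samples=time, n_features=channels).
    ``fit`` scans the model order from 1 upward, running ``restarts``
    seeded random initializations per order (multiplicative updates,
    Frobenius loss) and keeping the best reconstruction, until the VAF
    first exceeds ``vaf_threshold``.

    Attributes
    ----------
    weights_ : (channels, S) synergy matrix, columns max-normalized to 1
    activations_ : (S, time) temporal activations carrying the scale
    n_synergies_ : selected order
    vaf_by_order_ : best VAF per candidate order
    residual_norm_ : Frobenius norm of the residual at the selected order
    """

    def __init__(
        self,
        vaf_threshold: float = 0.80,
        restarts: int = 10,
        max_iter: int = 500,
        tol: float = 1e-6,
        max_synergies: int | None = None,
        random_state: int = 0,
    ) -> None:
        self.vaf_threshold = vaf_threshold
        self.restarts = restarts
        self.max_iter = max_iter
        self.tol = tol
        self.max_synergies = max_synergies
        self.random_state = random_state

    def fit(self, X, y=None):
        M = np.asarray(X, dtype=float).T  # channels x time
        if np.any(M < 0):
            raise ValueError("synergy input matrix must be non-negative")
        if not (0.0 < self.vaf_threshold < 1.0):
            raise ValueError("vaf_threshold must lie in (0, 1)")
        n_ch = M.shape[0]
        cap = min(self.max_synergies or n_ch, n_ch)
        total = float(np.linalg.norm(M) ** 2)
        if total == 0:
            raise ValueError("synergy input matrix is identically zero")

        vaf_by_order: list[float] = []
        best = None
        for S in range(1, cap + 1):
            best_err = np.inf
            best_WH = None
            for r in range(self.restarts):
                nmf = NMF(
                    n_components=S,
                    init="random",
                    solver="mu",
                    beta_loss="frobenius",
                    max_iter=self.max_iter,
                    tol=self.tol,
                    random_state=self.random_state * 1000 + 37 * S + r,
                )
                W = nmf.fit_transform(M)
                H = nmf.components_
                err = float(np.linalg.norm(M - W @ H))
                if err < best_err:
                    best_err, best_WH = err, (W, H)
            vaf = 1.0 - best_err**2 / total
            vaf_by_order.append(vaf)
            best = (best_WH[0], best_WH[1], S, best_err)
            if vaf >= self.vaf_threshold:
                break

        W, H, S, err = best
        # fold column scales into H so each synergy vector has max weight 1
        scale = W.max(axis=0)
        scale[scale == 0] = 1.0
        self.weights_ = W / scale
        self.activations_ = H * scale[:, None]
        self.n_synergies_ = S
        self.vaf_by_order_ = vaf_by_order
        self.residual_norm_ = err
        self.n_features_in_ = n_ch
        return self

    def transform(self, X) -> np.ndarray:
        """Project envelopes onto the fitted synergy vectors (NNLS-free
        least-squares projection clipped at zero), returning time x S."""
        M = np.asarray(X, dtype=float).T
        H, *_ = np.linalg.lstsq(self.weights_, M, rcond=None)
        return np.maximum(H, 0.0).T

    def to_synergy_set(self, labels: list[str] | None = None) -> SynergySet:
        return SynergySet(
            W=self.weights_.copy(),
            H=self.activations_.copy(),
            S=self.n_synergies_,
            vaf_by_order=list(self.vaf_by_order_),
            residual_norm=self.residual_norm_,
            labels=labels or [],
        )


def extract_synergies(
    M: EnvelopeMatrix | np.ndarray,
    vaf_threshold: float = 0.80,
    seed: int = 0,
    restarts: int = 10,
    max_iter: int = 500,
) -> SynergySet:
    """Factorize a (channels x time) envelope matrix; thin wrapper over
    :class:`SynergyExtractor`."""
    if isinstance(M, EnvelopeMatrix):
        labels = list(M.labels)
        values = M.values
        if M.dead_channels:
            keep = [i for i in range(values.shape[0]) if i not in M.dead_channels]
            values = values[keep]
            labels = [labels[i] for i in keep] if labels else []
    else:
        labels, values = [], np.asarray(M, dtype=float)
    ext = SynergyExtractor(
        vaf_threshold=vaf_threshold, restarts=restarts, max_iter=max_iter, random_state=seed
    ).fit(values.T)
    return ext.to_synergy_set(labels)


def coupling_from_W(
    syn: SynergySet, channel_groups: dict[str, str] | list[str]
) -> SynergyCoupling:
    """Aggregate the flexor-/extensor-dominated synergy vectors into group
    coupling scalars.

    ``channel_groups`` maps channel label (or gives per-channel entries in
    order) to "flexor"/"extensor"; other labels (e.g. lower trapezius) are
    excluded from both groups.  The dominant vector of a group is the W
    column with the largest mean weight over that group's channels; the
    coupling scalar is the mean weight of the named group within the named
    vector.
    """
    if syn.S < 2:
        raise ValueError("coupling requires at least two synergies")
    if isinstance(channel_groups, dict):
        if not syn.labels:
            raise ValueError("labeled channel_groups require a labeled SynergySet")
        groups = [channel_groups.get(lab, "other") for lab in syn.labels]
    else:
        groups = list(channel_groups)
    flx = [i for i, g in enumerate(groups) if g == "flexor"]
    ext = [i for i, g in enumerate(groups) if g == "extensor"]
    if not flx or not ext:
        raise ValueError("both flexor and extensor channels are required")

    mean_flx = syn.W[flx].mean(axis=0)  # per-column mean over flexor channels
    mean_ext = syn.W[ext].mean(axis=0)
    col_flx = int(np.argmax(mean_flx))  # flexor-dominated vector
    col_ext = int(np.argmax(mean_ext))  # extensor-dominated vector
    if col_flx == col_ext:
        raise ValueError(
            "degenerate synergies: the same vector dominates both muscle groups"
        )
    return SynergyCoupling(
        w_ext_flx=float(mean_flx[col_ext]),
        w_flx_flx=float(mean_flx[col_flx]),
        w_flx_ext=float(mean_ext[col_flx]),
        w_ext_ext=float(mean_ext[col_ext]),
    )


def antagonist_activation(
    a_primary: float, phase: str, coupling: SynergyCoupling
) -> float:
    """Synergy-coupled antagonist activation for the current movement phase.

    During extension ("Ext") the flexor group receives
    (w_ext_flx/w_flx_flx) * a_Ext; during flexion ("Flx") the extensor
    group receives (w_flx_ext/w_ext_ext) * a_Flx.  Clipped to
    [0.02, 1].
    """
    if not (0.0 <= a_primary <= 1.0):
        raise ValueError("primary activation must lie in [0, 1]")
    if phase == "Ext":
        ratio = coupling.ratio_flexor_during_ext
    elif phase == "Flx":
        ratio = coupling.ratio_extensor_during_flx
    else:
        raise ValueError(f"unknown phase {phase!r}; expected 'Ext' or 'Flx'")
    return float(np.clip(ratio * a_primary, A_FLOOR, 1.0))
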