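"""Partial-least-squares functional mode analysis (PLS-FMA).

Regresses a scalar functional property (here typically the fraction of native
contacts Q of a monomer) on flattened main-chain coordinates with PLS, and
extracts the collective mode maximally correlated with the property — the
coordinate-space direction of the fitted regression coefficients, normalised
to unit length. Model quality is quantified by the Pearson correlation
between model and data on a held-out validation set; frames must be
superposed on a common reference first (see :func:`align_frames`) so the mode
describes internal motion rather than rigid-body drift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import pearsonr
from sklearn.cross_decomposition import PLSRegression

from .structure import Structure

__all__ = ["FMAModel", "fit_fma", "mode_rmsf", "align_frames",
           "main_chain_mask", "kabsch"]

MAIN_CHAIN_ATOMS = ("N", "CA", "C", "O")


def main_chain_mask(structure: Structure) -> np.ndarray:
    """Boolean mask selecting the main-chain atoms N, Cα, C, O."""
    return np.isin(structure.atom_names, list(MAIN_CHAIN_ATOMS))


@dataclass
class FMAModel:
    """Fitted PLS-FMA model."""

    mode: np.ndarray  # (n_atoms, 3), unit Euclidean norm
    mean_coords: np.ndarray  # (n_atoms, 3) training-mean structure
    r_train: float
    r_val: float
    n_components: int
    train_frac: float
    _pls: PLSRegression = None  # type: ignore[assignment]
    _prop_mean: float = 0.0
    _prop_sd: float = 1.0

    def predict(self, frames: np.ndarray) -> np.ndarray:
        """Predict the property for frames of shape (n_frames, n_atoms, 3)."""
        X = np.asarray(frames).reshape(len(frames), -1) - self.mean_coords.ravel()
        z = self._pls.predict(X).ravel()
        return z * self._prop_sd + self._prop_mean


def fit_fma(frames: np.ndarray, prop: np.ndarray, n_components: int = 20,
            train_frac: float = 0.75, shuffle: bool = False,
            seed: int | None = None) -> FMAModel:
    """Fit PLS-FMA of a property on coordinates.

    By default the leading ``train_frac`` of frames (time-ordered block) is
    used for training and the rest for validation; ``shuffle=True`` draws a
    random split instead (reproducible via ``seed``). Coordinates are centred
    on the training mean and the property standardised before regression.
    """
    frames = np.asarray(frames, dtype=float)
    prop = np.asarray(prop, dtype=float).ravel()
    n_frames = len(frames)
    if len(prop) != n_frames:
        raise ValueError("property series length must equal frame count")
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must be in (0, 1)")
    if np.ptp(prop) == 0:
        raise ValueError("property is constant; correlation is undefined")

    idx = np.arange(n_frames)
    if shuffle:
        rng = np.random.default_rng(seed)
        idx = rng.permutation(idx)
    n_train = int(round(train_frac * n_frames))
    train, val = idx[:n_train], idx[n_train:]
    if n_components >= n_train:
        raise ValueError(f"n_components={n_components} must be < {n_train} training frames")

    X = frames.reshape(n_frames, -1)
    mean_x = X[train].mean(axis=0)
    y_mean, y_sd = prop[train].mean(), prop[train].std()
    Xc = X - mean_x
    yc = (prop - y_mean) / y_sd

    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(Xc[train], yc[train])
    pred = pls.predict(Xc).ravel()

    r_train = pearsonr(pred[train], yc[train]).statistic
    r_val = pearsonr(pred[val], yc[val]).statistic

    coef = np.asarray(pls.coef_).reshape(-1)
    mode = (coef / np.linalg.norm(coef)).reshape(-1, 3)

    return FMAModel(mode=mode, mean_coords=mean_x.reshape(-1, 3),
                    r_train=float(r_train), r_val=float(r_val),
                    n_components=n_components, train_frac=train_frac,
                    _pls=pls, _prop_mean=y_mean, _prop_sd=y_sd)


def mode_rmsf(model: FMAModel, atom_resids: np.ndarray) -> dict:
    """Per-residue amplitude of the mode, for structure colouring.

    The amplitude of a residue is the root-sum-square of its atoms' mode
    3-vectors, so the squared amplitudes over residues partition the unit
    norm of the mode (Σ amp² = 1) and rank residues by their contribution to
    the property change.
    """
    atom_resids = np.asarray(atom_resids)
    if len(atom_resids) != len(model.mode):
        raise ValueError(
            f"atom→residue map has {len(atom_resids)} entries for "
            f"{len(model.mode)} mode atoms")
    sq = np.sum(model.mode ** 2, axis=1)
    out = {}
    for rid in np.unique(atom_resids):
        out[int(rid)] = float(np.sqrt(sq[atom_resids == rid].sum()))
    return out


def kabsch(mobile: np.ndarray, target: np.ndarray):
    """Least-squares superposition: rotation R and translation t minimising
    ||(mobile @ R.T + t) - target||. Proper rotation (det +1) enforced."""
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    mu_m, mu_t = mobile.mean(axis=0), target.mean(axis=0)
    A = mobile - mu_m
    B = target - mu_t
    if np.linalg.matrix_rank(A) < 2:
        raise ValueError("degenerate (collinear) selection; superposition undefined")
    H = A.T @ B
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = mu_t - R @ mu_m
    return R, t


def align_frames(frames: np.ndarray, reference: np.ndarray,
                 selection: np.ndarray | None = None) -> np.ndarray:
    """Superpose each frame onto the reference over a selection of atoms.

    ``selection`` is an index or boolean array over atoms (default: all);
    the fitted transform is applied to all atoms of the frame. RMSD over the
    selection never increases.
    """
    frames = np.asarray(frames, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if selection is None:
        sel = np.arange(frames.shape[1])
    else:
        sel = np.asarray(selection)
        if sel.dtype == bool:
            sel = np.flatnonzero(sel)
    if len(sel) == 0:
        raise ValueError("empty selection")
    out = np.empty_like(frames)
    ref_sel = reference[sel]
    for k, frame in enumerate(frames):
        R, t = kabsch(frame[sel], ref_sel)
        out[k] = frame @ R.T + t
    return out
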