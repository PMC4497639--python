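"""Two-dimensional coding-space of neuron selectivities (PCA + separators).

The neurons × 12 selectivity matrix is reduced by a principal component
analysis on centred (not variance-scaled) columns; components are retained
by the Kaiser-Guttman criterion — keep every PC whose variance fraction
exceeds that of a single original variable (1/12 ≈ 8.3%).  In practice two
PCs survive: PC1 loads on the motion scores (movement sensitivity) and PC2
on the position scores (posture sensitivity).

Sign conventions are canonicalised so results are reproducible: PC1 is
oriented so movement-*selective* neurons project to the negative side (a
movement-indifferent neuron lands in the right half of the space), and PC2
so dorsal position selectivity is positive.  Because dorsal and ventral
specimens of position-sensitive types mirror each other, the analysis also
reports |PC2| ("the negative part of PC2 flipped over").

Two axis-aligned linear thresholds classify neurons into the four major
groups: the *posture* threshold on |PC2| splits position-sensitive (SP/DP)
from motion-only (ON/OFF) types, and the *movement* threshold on PC1 splits
movement-activated (ON/DP) from movement-suppressed-or-indifferent (OFF/SP)
types.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .errors import DegenerateSpaceError, InvalidParameterError, ThresholdError
from .selectivity import SCORE_COLUMNS, SCORE_TYPES

KG_FRACTION = 1.0 / 12.0
MOTION_COLS = [i for i, c in enumerate(SCORE_COLUMNS) if c.startswith("motion")]
POSITION_COLS = [i for i, c in enumerate(SCORE_COLUMNS) if c.startswith("position")]

MOVEMENT_GROUPS = frozenset({"ON", "DP"})   # movement-activated, left of the movement threshold
POSTURE_GROUPS = frozenset({"SP", "DP"})    # position-sensitive, above the posture threshold


@dataclass
class CodingSpaceModel:
    """Fitted PCA coding-space with orientation and separator state."""

    mean_: np.ndarray                 # column means (12,)
    loadings: np.ndarray              # (n_components, 12), orthonormal rows
    variance_fractions: np.ndarray    # per-PC fraction of total variance
    n_retained: int
    kg_threshold: float = KG_FRACTION
    movement_threshold: float | None = None  # on PC1
    posture_threshold: float | None = None   # on |PC2|
    columns: tuple = tuple(SCORE_COLUMNS)

    def to_json(self) -> str:
        return json.dumps({
            "mean": self.mean_.tolist(),
            "loadings": self.loadings.tolist(),
            "variance_fractions": self.variance_fractions.tolist(),
            "n_retained": self.n_retained,
            "kg_threshold": self.kg_threshold,
            "movement_threshold": self.movement_threshold,
            "posture_threshold": self.posture_threshold,
            "columns": list(self.columns),
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "CodingSpaceModel":
        d = json.loads(text)
        return cls(
            mean_=np.asarray(d["mean"]),
            loadings=np.asarray(d["loadings"]),
            variance_fractions=np.asarray(d["variance_fractions"]),
            n_retained=int(d["n_retained"]),
            kg_threshold=float(d["kg_threshold"]),
            movement_threshold=d["movement_threshold"],
            posture_threshold=d["posture_threshold"],
            columns=tuple(d["columns"]),
        )


@dataclass
class CodingSpaceCoords:
    """Projections of neurons into the coding-space."""

    pc1: np.ndarray
    pc2_signed: np.ndarray
    index: pd.Index | None = None
    groups: np.ndarray | None = None

    @property
    def pc2_abs(self) -> np.ndarray:
        return np.abs(self.pc2_signed)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"pc1": self.pc1, "pc2_signed": self.pc2_signed,
                           "pc2_abs": self.pc2_abs}, index=self.index)
        if self.groups is not None:
            df["group"] = self.groups
        return df


def _as_matrix(matrix) -> np.ndarray:
    x = matrix.to_numpy(dtype=float) if isinstance(matrix, pd.DataFrame) else \
        np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[1] != len(SCORE_COLUMNS):
        raise InvalidParameterError(
            f"selectivity matrix must have {len(SCORE_COLUMNS)} columns "
            f"({', '.join(SCORE_COLUMNS)}); got shape {x.shape}"
        )
    return x


def fit_coding_space(matrix) -> CodingSpaceModel:
    """Fit the PCA coding-space to a neurons × 12 selectivity matrix."""
    x = _as_matrix(matrix)
    if x.shape[0] < 3:
        raise InvalidParameterError("at least 3 neurons are required")
    if np.abs(x).max() > 1 + 1e-9:
        raise InvalidParameterError("selectivity scores must lie within [-1, 1]")
    pca = PCA()
    pca.fit(x)
    ev = pca.explained_variance_
    if np.sum(ev > 1e-12 * max(ev.max(), 1.0)) < 2:
        raise DegenerateSpaceError("fewer than 2 non-degenerate principal components")
    loadings = _canonicalize_signs(pca.components_)
    fractions = pca.explained_variance_ratio_
    return CodingSpaceModel(
        mean_=pca.mean_,
        loadings=loadings,
        variance_fractions=fractions,
        n_retained=int(np.sum(fractions > KG_FRACTION)),
    )


def _canonicalize_signs(components: np.ndarray) -> np.ndarray:
    out = components.copy()
    # PC1: movement-selective neurons (high motion scores) on the negative side
    if out[0, MOTION_COLS].sum() > 0:
        out[0] *= -1
    # PC2: dorsal position selectivity positive
    if out.shape[0] > 1 and out[1, POSITION_COLS].sum() < 0:
        out[1] *= -1
    # remaining PCs: largest-|loading| element positive
    for i in range(2, out.shape[0]):
        j = np.argmax(np.abs(out[i]))
        if out[i, j] < 0:
            out[i] *= -1
    return out


def project(matrix, model: CodingSpaceModel) -> CodingSpaceCoords:
    """Project selectivity vectors into the fitted coding-space.

    Accepts a neurons × 12 matrix/DataFrame, one 12-vector, or a
    ``SelectivityVector``.
    """
    if model.loadings is None or model.loadings.size == 0:
        raise InvalidParameterError("model is not fitted")
    if hasattr(matrix, "to_series"):  # SelectivityVector
        matrix = matrix.to_series().to_frame().T
    index = matrix.index if isinstance(matrix, pd.DataFrame) else None
    x = matrix.to_numpy(dtype=float) if isinstance(matrix, pd.DataFrame) else \
        np.atleast_2d(np.asarray(matrix, dtype=float))
    if x.shape[1] != model.mean_.size:
        raise InvalidParameterError("column count does not match the fitted model")
    s = (x - model.mean_) @ model.loadings.T
    return CodingSpaceCoords(pc1=s[:, 0], pc2_signed=s[:, 1], index=index)


def classify(coords: CodingSpaceCoords, model: CodingSpaceModel) -> np.ndarray:
    """Assign each projected neuron to {SP, DP, ON, OFF} via the two thresholds."""
    if model.movement_threshold is None or model.posture_threshold is None:
        raise ThresholdError("separator thresholds are not set; call fit_thresholds first")
    moving = coords.pc1 < model.movement_threshold
    postural = coords.pc2_abs > model.posture_threshold
    out = np.where(postural, np.where(moving, "DP", "SP"),
                   np.where(moving, "ON", "OFF")).astype("<U5")
    bad = ~(np.isfinite(coords.pc1) & np.isfinite(coords.pc2_signed))
    out[bad] = "other"
    return out


def _axis_threshold(values: np.ndarray, on_side: np.ndarray, axis_name: str) -> float:
    """Midpoint of the gap between the two groups' extreme coordinates.

    ``on_side`` marks the group expected on the *low* side of the axis.  If
    the groups overlap, a warning is raised and the maximum-accuracy split is
    returned instead.
    """
    lo, hi = values[on_side], values[~on_side]
    if lo.size == 0 or hi.size == 0:
        warnings.warn(f"only one group present on the {axis_name} axis; threshold is degenerate")
        return float(values.max() + 1.0) if hi.size == 0 else float(values.min() - 1.0)
    if lo.max() < hi.min():
        return float((lo.max() + hi.min()) / 2.0)
    warnings.warn(f"groups overlap on the {axis_name} axis; using max-accuracy split")
    cand = np.sort(np.unique(values))
    mids = (cand[:-1] + cand[1:]) / 2.0
    acc = [np.mean((values <= m) == on_side) for m in mids]
    return float(mids[int(np.argmax(acc))])


def fit_thresholds(coords: CodingSpaceCoords, labels, model: CodingSpaceModel) -> float:
    """Fit the two axis-aligned thresholds from labelled coordinates.

    ``labels`` are true group names; only SP/DP/ON/OFF rows participate.
    Sets ``model.movement_threshold`` / ``model.posture_threshold`` in place
    and returns the training accuracy over those four groups.
    """
    labels = np.asarray(labels)
    core = np.isin(labels, ["SP", "DP", "ON", "OFF"])
    if core.sum() < 2:
        raise ThresholdError("need labelled SP/DP/ON/OFF neurons to fit thresholds")
    lab = labels[core]
    pc1 = coords.pc1[core]
    p2 = coords.pc2_abs[core]
    model.movement_threshold = _axis_threshold(pc1, np.isin(lab, list(MOVEMENT_GROUPS)), "movement")
    # posture axis: SP/DP on the high side
    model.posture_threshold = -_axis_threshold(-p2, np.isin(lab, list(POSTURE_GROUPS)), "posture")
    sub = CodingSpaceCoords(pc1=pc1, pc2_signed=coords.pc2_signed[core])
    return float(np.mean(classify(sub, model) == lab))


def resample_variance(
    matrix,
    mode: str = "bootstrap50",
    reps: int = 100,
    rng=None,
    labels=None,
    n_draw: int = 50,
    n_per_group: int = 6,
) -> pd.DataFrame:
    """Stability of per-PC variance fractions under resampling.

    ``bootstrap50``: draw ``n_draw`` neurons with replacement and refit.
    ``balanced6x5``: first select ``n_per_group`` neurons per labelled group
    (without replacement), then draw ``n_draw`` with replacement from that
    balanced pool, and refit.  Returns mean ± SD of each PC's variance
    fraction across repetitions, plus the count of degenerate draws skipped.
    """
    x = _as_matrix(matrix)
    rng = np.random.default_rng(rng)
    if mode not in ("bootstrap50", "balanced6x5"):
        raise InvalidParameterError("mode must be 'bootstrap50' or 'balanced6x5'")
    if mode == "balanced6x5":
        if labels is None:
            raise InvalidParameterError("balanced mode requires group labels")
        labels = np.asarray(labels)
        groups = np.unique(labels)
        for g in groups:
            if (labels == g).sum() < n_per_group:
                raise InvalidParameterError(
                    f"group {g!r} has fewer than {n_per_group} members for balanced resampling")
    fracs, skipped = [], 0
    for _ in range(reps):
        if mode == "bootstrap50":
            pool = rng.integers(0, x.shape[0], size=n_draw)
        else:
            sel = np.concatenate([
                rng.choice(np.flatnonzero(labels == g), size=n_per_group, replace=False)
                for g in groups
            ])
            pool = rng.choice(sel, size=n_draw, replace=True)
        try:
            m = fit_coding_space(x[pool])
        except DegenerateSpaceError:
            skipped += 1
            continue
        f = np.zeros(x.shape[1])
        f[: m.variance_fractions.size] = m.variance_fractions
        fracs.append(f)
    if not fracs:
        raise DegenerateSpaceError("every resampling draw was degenerate")
    arr = np.asarray(fracs)
    df = pd.DataFrame({
        "pc": np.arange(1, x.shape[1] + 1),
        "mean_fraction": arr.mean(axis=0),
        "sd_fraction": arr.std(axis=0),
    })
    df.attrs["skipped"] = skipped
    df.attrs["reps_used"] = len(fracs)
    return df


def align_loadings(loadings: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Match PCs to a reference basis up to order and sign (greedy by |dot|)."""
    k = min(loadings.shape[0], reference.shape[0])
    out = np.zeros((k, loadings.shape[1]))
    used = set()
    for i in range(k):
        dots = loadings @ reference[i]
        order = np.argsort(-np.abs(dots))
        j = next(j for j in order if j not in used)
        used.add(j)
        out[i] = loadings[j] * np.sign(dots[j])
    return out
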