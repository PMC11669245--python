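"""Three-class random-forest voxel classification of IBA-1 stacks.

Sparse expert labels (microglia / vasculature / background) plus the filter
bank of :mod:`microglia3d.features` train a random forest that assigns each
voxel a probability triple.  Only labelled voxels' features are materialized
for training; prediction builds the dense feature matrix once and evaluates
the forest in voxel chunks, which is exactly equivalent to whole-stack
evaluation.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .core import CLASSES, ProbabilityMap, Stack
from .features import FeatureBank, extract_features


@dataclass
class SparseLabelMap:
    """Sparse voxel annotations: per-class ``(n, 3)`` index arrays."""

    coords: dict[str, np.ndarray] = field(default_factory=dict)
    shape: tuple[int, int, int] | None = None

    def __post_init__(self) -> None:
        clean = {}
        for cls, arr in self.coords.items():
            if cls not in CLASSES:
                raise ValueError(f"unknown class {cls!r}; expected one of {CLASSES}")
            arr = np.asarray(arr, dtype=np.int64).reshape(-1, 3)
            clean[cls] = arr
            if self.shape is not None and len(arr):
                if (arr < 0).any() or (arr >= np.array(self.shape)).any():
                    raise ValueError(f"{cls} labels outside stack bounds {self.shape}")
        self.coords = clean
        # a voxel may carry exactly one class
        seen: dict[tuple, str] = {}
        for cls in CLASSES:
            for c in map(tuple, self.coords.get(cls, [])):
                if c in seen and seen[c] != cls:
                    raise ValueError(f"voxel {c} labelled both {seen[c]} and {cls}")
                seen[c] = cls

    def n_labels(self, cls: str) -> int:
        return len(self.coords.get(cls, ()))

    def require_all_classes(self) -> None:
        for cls in CLASSES:
            if self.n_labels(cls) == 0:
                raise ValueError(f"training requires at least one label of class {cls!r}")

    def stacked(self) -> tuple[np.ndarray, np.ndarray]:
        """All coords and integer class targets, in fixed class order."""
        cs, ys = [], []
        for k, cls in enumerate(CLASSES):
            arr = self.coords.get(cls)
            if arr is not None and len(arr):
                cs.append(arr)
                ys.append(np.full(len(arr), k, dtype=np.int64))
        if not cs:
            return np.empty((0, 3), np.int64), np.empty(0, np.int64)
        return np.concatenate(cs), np.concatenate(ys)

    # CSV interchange: columns z, y, x, class -------------------------------
    def to_csv(self, path) -> None:
        import pandas as pd

        coords, y = self.stacked()
        df = pd.DataFrame(
            {"z": coords[:, 0], "y": coords[:, 1], "x": coords[:, 2],
             "class": [CLASSES[k] for k in y]}
        )
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, shape=None) -> "SparseLabelMap":
        import pandas as pd

        df = pd.read_csv(path)
        coords = {
            c: df.loc[df["class"] == c, ["z", "y", "x"]].to_numpy()
            for c in df["class"].unique()
        }
        return cls(coords=coords, shape=shape)


def sample_sparse_labels(
    truth_labels: np.ndarray,
    n_cells: int,
    n_per_class: int,
    seed: int,
    background_margin: int = 2,
) -> SparseLabelMap:
    """Draw sparse training labels from a ground-truth label volume.

    Emulates expert annotation on a synthetic scene: random voxels inside
    cells, inside vessels, and in the background (kept ``background_margin``
    voxels away from any object so annotators' conservative background
    strokes are mirrored).
    """
    from scipy import ndimage

    rng = np.random.default_rng(seed)
    out = {}
    cell_mask = (truth_labels >= 1) & (truth_labels <= n_cells)
    vessel_mask = truth_labels > n_cells
    bg = truth_labels == 0
    if background_margin > 0:
        bg &= ~ndimage.binary_dilation(~bg, iterations=background_margin)
    for cls, mask in (
        ("microglia", cell_mask),
        ("vasculature", vessel_mask),
        ("background", bg),
    ):
        coords = np.argwhere(mask)
        if len(coords) == 0:
            continue
        pick = rng.choice(len(coords), size=min(n_per_class, len(coords)), replace=False)
        out[cls] = coords[np.sort(pick)]
    return SparseLabelMap(coords=out, shape=truth_labels.shape)


@dataclass
class VoxelClassifier:
    """A trained forest bound to the exact feature-bank configuration."""

    forest: RandomForestClassifier
    bank: FeatureBank
    spacing_hint: tuple[float, float, float] | None = None
    oob_score: float | None = None

    def predict_probabilities(
        self,
        stack: Stack | np.ndarray,
        bank: FeatureBank | None = None,
        chunk_voxels: int = 2_000_000,
    ) -> ProbabilityMap:
        """Per-voxel probability triples for a single-channel stack.

        ``bank``, if given, must equal the training configuration; chunked
        forest evaluation is bit-identical to whole-stack evaluation.
        """
        if bank is not None and bank != self.bank:
            raise ValueError(
                "feature bank mismatch between training and prediction; "
                "retrain or pass the classifier's own bank"
            )
        if isinstance(stack, Stack):
            vol = stack.data
            spacing = stack.spacing
        else:
            vol = np.asarray(stack)
            spacing = self.spacing_hint or (1.0, 1.0, 1.0)
        if vol.ndim == 4:
            raise ValueError("predict on a single channel (use stack.channel(...))")
        feats = extract_features(vol, self.bank, spacing)
        n = feats.shape[0]
        probs = np.empty((n, len(CLASSES)), dtype=np.float32)
        for start in range(0, n, chunk_voxels):
            sl = slice(start, min(start + chunk_voxels, n))
            probs[sl] = self._proba(feats[sl])
        del feats
        out = probs.T.reshape((len(CLASSES),) + vol.shape)
        # renormalize away float32 rounding so the sum-to-one contract holds
        out /= out.sum(axis=0, keepdims=True)
        return ProbabilityMap(probs=out, spacing=spacing)

    def _proba(self, X: np.ndarray) -> np.ndarray:
        """Probabilities in fixed CLASSES order regardless of fit ordering."""
        raw = self.forest.predict_proba(X)
        out = np.zeros((X.shape[0], len(CLASSES)), dtype=np.float64)
        for j, k in enumerate(self.forest.classes_):
            out[:, int(k)] = raw[:, j]
        return out

    def accuracy(self, stack: Stack | np.ndarray, labels: SparseLabelMap) -> float:
        """Argmax accuracy on a validation label set."""
        coords, y = labels.stacked()
        if isinstance(stack, Stack):
            vol, spacing = stack.data, stack.spacing
        else:
            vol, spacing = np.asarray(stack), self.spacing_hint or (1.0, 1.0, 1.0)
        X = extract_features(vol, self.bank, spacing, coords=coords)
        pred = np.argmax(self._proba(X), axis=1)
        return float(np.mean(pred == y))

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(
                {
                    "forest": self.forest,
                    "bank": self.bank.to_dict(),
                    "spacing_hint": self.spacing_hint,
                    "oob_score": self.oob_score,
                },
                fh,
            )

    @classmethod
    def load(cls, path) -> "VoxelClassifier":
        with open(path, "rb") as fh:
            d = pickle.load(fh)
        return cls(
            forest=d["forest"],
            bank=FeatureBank.from_dict(d["bank"]),
            spacing_hint=d["spacing_hint"],
            oob_score=d["oob_score"],
        )


def train_classifier(
    stack: Stack | np.ndarray,
    labels: SparseLabelMap,
    bank: FeatureBank | None = None,
    n_trees: int = 100,
    max_depth: int | None = None,
    seed: int = 0,
    compute_oob: bool = False,
    spacing: tuple[float, float, float] | None = None,
) -> VoxelClassifier:
    """Train the three-class voxel forest on sparse labels.

    Labelled voxels are sorted into a canonical order before fitting, so the
    result is invariant to the order in which annotations were drawn
    (deterministic given ``seed``).
    """
    labels.require_all_classes()
    bank = bank or FeatureBank()
    if isinstance(stack, Stack):
        vol, sp = stack.data, stack.spacing
    else:
        vol = np.asarray(stack)
        sp = spacing or (1.0, 1.0, 1.0)
    coords, y = labels.stacked()
    # canonical voxel order (coords are unique): training is invariant to
    # annotation order and symmetric under class relabelling
    order = np.lexsort((coords[:, 2], coords[:, 1], coords[:, 0]))
    coords, y = coords[order], y[order]
    X = extract_features(vol, bank, sp, coords=coords)
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        max_depth=max_depth,
        random_state=int(seed),
        n_jobs=1,
        oob_score=compute_oob,
        bootstrap=True,
    )
    forest.fit(X, y)
    return VoxelClassifier(
        forest=forest,
        bank=bank,
        spacing_hint=sp,
        oob_score=float(forest.oob_score_) if compute_oob else None,
    )
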