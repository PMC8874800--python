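"""Sliding-window feature vectors and mode-based window labels.

Classification operates on a 13-step moving window (0.15 s at 89 Hz)
shifted one step at a time.  Each window yields 21 features: the means of
the 12 controller-in-{H} pose variables (position and orientation of both
controllers), the sample SDs of the 6 controller orientation angles, and
the Pearson correlations of the three homologous angle pairs
(gamma_R, gamma_L), (beta_R, beta_L), (alpha_R, alpha_L).  The window's
true class is the mode of its per-step labels (>= 7 of 13 steps).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .session import NO_MOVEMENT, SessionValidationError

__all__ = ["FeatureSpec", "WindowDataset", "window_label", "window_features", "build_dataset"]

DEFAULT_WINDOW_STEPS = 13

_MEAN_VARS = tuple(
    f"{c}_H_{dev}" for dev in ("R", "L") for c in ("X", "Y", "Z", "gamma", "beta", "alpha")
)
_SD_VARS = tuple(f"{c}_H_{dev}" for dev in ("R", "L") for c in ("gamma", "beta", "alpha"))
_CORR_PAIRS = tuple((f"{c}_H_R", f"{c}_H_L") for c in ("gamma", "beta", "alpha"))


@dataclass(frozen=True)
class FeatureSpec:
    """Which window statistics form the feature vector.

    Defaults give the canonical 21 features (12 means + 6 SDs + 3
    correlations).  An alternative SD set using the right controller's
    position and orientation can be configured.
    """

    mean_vars: tuple[str, ...] = _MEAN_VARS
    sd_vars: tuple[str, ...] = _SD_VARS
    corr_pairs: tuple[tuple[str, str], ...] = _CORR_PAIRS
    window_steps: int = DEFAULT_WINDOW_STEPS

    def __post_init__(self) -> None:
        if self.window_steps < 2:
            raise ValueError("window must span at least 2 steps")

    @property
    def n_features(self) -> int:
        return len(self.mean_vars) + len(self.sd_vars) + len(self.corr_pairs)

    @property
    def feature_names(self) -> list[str]:
        return (
            [f"mean_{v}" for v in self.mean_vars]
            + [f"sd_{v}" for v in self.sd_vars]
            + [f"corr_{a}__{b}" for a, b in self.corr_pairs]
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "mean_vars": list(self.mean_vars),
                "sd_vars": list(self.sd_vars),
                "corr_pairs": [list(p) for p in self.corr_pairs],
                "window_steps": self.window_steps,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "FeatureSpec":
        obj = json.loads(text)
        return cls(
            mean_vars=tuple(obj["mean_vars"]),
            sd_vars=tuple(obj["sd_vars"]),
            corr_pairs=tuple(tuple(p) for p in obj["corr_pairs"]),
            window_steps=int(obj["window_steps"]),
        )


@dataclass
class WindowDataset:
    """Per-window features and class labels for classifier training."""

    features: pd.DataFrame  # one row per window, FeatureSpec column order
    labels: np.ndarray  # per-window true class
    starts: np.ndarray  # window start indices into the variable table
    spec: FeatureSpec = field(default_factory=FeatureSpec)
    classes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.features) != len(self.labels):
            raise SessionValidationError("features and labels must be aligned")
        if not self.classes:
            self.classes = tuple(sorted(set(self.labels)))

    def __len__(self) -> int:
        return len(self.features)

    def to_frame(self) -> pd.DataFrame:
        out = self.features.copy()
        out.insert(0, "start", self.starts)
        out["label"] = self.labels
        return out


def window_label(classes) -> str:
    """Mode of the per-step labels within one window.

    With a 13-step window a class held by 7 or more steps wins outright.
    Tied modes (possible only with 3+ classes in one window, or even
    window lengths) break deterministically toward the class occurring
    earliest in the window.
    """
    classes = list(classes)
    if not classes:
        raise SessionValidationError("empty window")
    counts: dict[str, int] = {}
    first: dict[str, int] = {}
    for i, c in enumerate(classes):
        counts[c] = counts.get(c, 0) + 1
        first.setdefault(c, i)
    best = max(counts.values())
    tied = [c for c, n in counts.items() if n == best]
    return min(tied, key=first.__getitem__)


def window_features(table_slice: pd.DataFrame, spec: FeatureSpec | None = None) -> np.ndarray:
    """The feature vector for one full window (fixed order, length 21).

    Sample (ddof=1) SDs; Pearson correlations, reported as 0 when either
    column of a pair has zero variance (a constant window carries no
    co-variation information).
    """
    spec = spec or FeatureSpec()
    if len(table_slice) != spec.window_steps:
        raise SessionValidationError(
            f"window must have exactly {spec.window_steps} rows"
        )
    values: list[float] = []
    for v in spec.mean_vars:
        values.append(float(table_slice[v].mean()))
    for v in spec.sd_vars:
        values.append(float(table_slice[v].std(ddof=1)))
    for a, b in spec.corr_pairs:
        xa = table_slice[a].to_numpy(float)
        xb = table_slice[b].to_numpy(float)
        if xa.std() == 0.0 or xb.std() == 0.0:
            values.append(0.0)
        else:
            values.append(float(np.corrcoef(xa, xb)[0, 1]))
    return np.asarray(values)


def build_dataset(
    table: pd.DataFrame,
    labels: np.ndarray | None = None,
    spec: FeatureSpec | None = None,
) -> WindowDataset:
    """Stride-1 sliding windows over a labelled variable table.

    An N-row table yields N - window + 1 windows.  Per-step labels
    default to the table's ``labels`` attribute (set by the assembly
    step from the session's ground truth).
    """
    spec = spec or FeatureSpec()
    if labels is None:
        labels = table.attrs.get("labels")
    if labels is None:
        raise SessionValidationError("per-step labels are required")
    labels = np.asarray(labels, dtype=object)
    if len(labels) != len(table):
        raise SessionValidationError("labels must match table length")
    w = spec.window_steps
    n_windows = len(table) - w + 1
    if n_windows < 1:
        raise SessionValidationError("table shorter than one window")

    cols = {v for v in spec.mean_vars} | set(spec.sd_vars) | {
        c for pair in spec.corr_pairs for c in pair
    }
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise SessionValidationError(f"table missing feature variables: {missing}")

    # Vectorized via sliding windows; equivalent to per-window calls.
    from numpy.lib.stride_tricks import sliding_window_view

    feats: dict[str, np.ndarray] = {}
    for v in spec.mean_vars:
        win = sliding_window_view(table[v].to_numpy(float), w)
        feats[f"mean_{v}"] = win.mean(axis=1)
    for v in spec.sd_vars:
        win = sliding_window_view(table[v].to_numpy(float), w)
        feats[f"sd_{v}"] = win.std(axis=1, ddof=1)
    for a, b in spec.corr_pairs:
        wa = sliding_window_view(table[a].to_numpy(float), w)
        wb = sliding_window_view(table[b].to_numpy(float), w)
        ca = wa - wa.mean(axis=1, keepdims=True)
        cb = wb - wb.mean(axis=1, keepdims=True)
        sa = np.sqrt((ca**2).sum(axis=1))
        sb = np.sqrt((cb**2).sum(axis=1))
        denom = sa * sb
        corr = np.zeros(n_windows)
        ok = denom > 0
        corr[ok] = (ca * cb).sum(axis=1)[ok] / denom[ok]
        feats[f"corr_{a}__{b}"] = np.clip(corr, -1.0, 1.0)

    features = pd.DataFrame({name: feats[name] for name in spec.feature_names})
    window_labels = np.asarray(
        [window_label(labels[i : i + w]) for i in range(n_windows)], dtype=object
    )
    return WindowDataset(
        features=features,
        labels=window_labels,
        starts=np.arange(n_windows),
        spec=spec,
    )
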