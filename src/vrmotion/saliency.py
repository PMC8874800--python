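"""Spectral-gap PCA saliency: which variables characterize each movement.

For every repetition segment the 30 kinematic time series are each
normalized by their own within-segment SD, a 30x30 population covariance
matrix K_n is formed (the correlation matrix of the moving variables),
and its eigenvalues are sorted in descending order.  The *spectral gap*
— the largest difference between consecutive eigenvalues — separates
dominant components from the noise floor; the eigenvalues preceding the
gap are dominant.  Within each dominant eigenvector the absolute loadings
are sorted descending and the same largest-consecutive-drop rule selects
the salient variables.  Per-gesture salient sets are the union of the
per-repetition selections, with occurrence counts.

For a single coordinated out-and-back movement one principal component
suffices: all smoothly moving variables share one time course, so the
spectrum shows a single dominant eigenvalue.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinematics import VARIABLE_NAMES
from .segmentation import Segment
from .session import SessionValidationError

__all__ = [
    "CovarianceSpectrum",
    "SalientSet",
    "normalize_segment",
    "covariance",
    "spectral_gap_count",
    "loading_gap_select",
    "aggregate_saliency",
    "SaliencyModel",
    "SaliencyResults",
]


@dataclass
class CovarianceSpectrum:
    """Covariance matrix of one segment with its eigendecomposition."""

    segment_index: int
    matrix: np.ndarray
    eigenvalues: np.ndarray  # sorted descending
    eigenvectors: np.ndarray  # columns aligned with eigenvalues

    def __post_init__(self) -> None:
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise SessionValidationError("covariance matrix must be symmetric")
        if not np.isclose(self.eigenvalues.sum(), np.trace(self.matrix), atol=1e-6):
            raise SessionValidationError("eigenvalues do not sum to the trace")


@dataclass
class SalientSet:
    """Salient variable names for one movement class, with provenance."""

    label: str
    variables: list[str]
    counts: dict[str, int] = field(default_factory=dict)
    per_segment: list[list[str]] = field(default_factory=list)


def normalize_segment(table_slice: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Scale each column by its within-segment SD (population, ddof=0).

    Returns the normalized slice and the list of zero-SD columns, which
    are passed through unscaled.
    """
    if len(table_slice) < 2:
        raise SessionValidationError("segment must have at least 2 rows")
    sd = table_slice.std(ddof=0)
    flagged = list(sd.index[sd == 0.0])
    safe = sd.replace(0.0, 1.0)
    return table_slice / safe, flagged


def covariance(normalized: pd.DataFrame, segment_index: int = 0) -> CovarianceSpectrum:
    """Population covariance of the normalized columns, eigendecomposed.

    Entries are means over the segment of the products of mean-removed
    columns (divide-by-N covariance).  Eigenvalues are returned sorted
    descending with their eigenvectors aligned.
    """
    values = normalized.to_numpy(dtype=float)
    if values.shape[0] < 2:
        raise SessionValidationError("need at least 2 rows for covariance")
    if not np.all(np.isfinite(values)):
        raise SessionValidationError("non-finite values in segment slice")
    centered = values - values.mean(axis=0)
    K = centered.T @ centered / values.shape[0]
    K = 0.5 * (K + K.T)  # guard symmetry against rounding
    lam, vec = np.linalg.eigh(K)
    order = np.argsort(lam)[::-1]
    return CovarianceSpectrum(segment_index, K, lam[order], vec[:, order])


def _gap_position(values: np.ndarray) -> int:
    """Index i such that the largest drop is values[i] - values[i+1].

    Ties break toward the earliest position (fewer retained components).
    """
    diffs = values[:-1] - values[1:]
    return int(np.argmax(diffs))


def spectral_gap_count(eigenvalues: np.ndarray) -> int:
    """Number of dominant eigenvalues: those preceding the largest gap."""
    eigenvalues = np.asarray(eigenvalues, float)
    if eigenvalues.shape[0] < 2:
        raise SessionValidationError("need at least 2 eigenvalues")
    return _gap_position(eigenvalues) + 1


def loading_gap_select(eigenvector: np.ndarray, names=VARIABLE_NAMES) -> list[str]:
    """Variables whose |loading| precedes the largest consecutive drop.

    Returned in descending-loading order.
    """
    loadings = np.abs(np.asarray(eigenvector, float))
    if loadings.shape[0] != len(names):
        raise SessionValidationError("eigenvector length must match variable names")
    order = np.argsort(loadings)[::-1]
    sorted_loadings = loadings[order]
    keep = _gap_position(sorted_loadings) + 1
    return [names[i] for i in order[:keep]]


def aggregate_saliency(
    per_segment_salient: list[list[str]], labels: list[str]
) -> dict[str, SalientSet]:
    """Union per-repetition salient variables by movement class, with counts.

    Variables are ordered by occurrence count (descending), ties by first
    appearance.
    """
    if len(per_segment_salient) != len(labels):
        raise SessionValidationError("salient lists and labels must be aligned")
    out: dict[str, SalientSet] = {}
    for salient, label in zip(per_segment_salient, labels):
        entry = out.setdefault(label, SalientSet(label, [], {}, []))
        entry.per_segment.append(list(salient))
        for name in salient:
            entry.counts[name] = entry.counts.get(name, 0) + 1
    for entry in out.values():
        first_seen = {}
        for i, name in enumerate(
            n for salient in entry.per_segment for n in salient
        ):
            first_seen.setdefault(name, i)
        entry.variables = sorted(
            entry.counts, key=lambda n: (-entry.counts[n], first_seen[n])
        )
    return out


class SaliencyModel:
    """Per-segment PCA saliency analysis of a 30-variable kinematic table.

    Parameters
    ----------
    table : DataFrame
        The kinematic variable table (30 canonical columns).
    segments : list of Segment
        Labelled repetition segments indexing into ``table`` rows.

    ``fit()`` returns a :class:`SaliencyResults`.
    """

    def __init__(self, table: pd.DataFrame, segments: list[Segment]):
        missing = [c for c in VARIABLE_NAMES if c not in table.columns]
        if missing:
            raise SessionValidationError(f"table missing variables: {missing}")
        if not segments:
            raise SessionValidationError("at least one segment is required")
        self.table = table
        self.segments = segments

    def fit(self) -> "SaliencyResults":
        spectra: list[CovarianceSpectrum] = []
        dominant_counts: list[int] = []
        per_segment_salient: list[list[str]] = []
        for idx, seg in enumerate(self.segments):
            chunk = self.table.iloc[seg.start : seg.end][list(VARIABLE_NAMES)]
            normalized, _ = normalize_segment(chunk)
            spectrum = covariance(normalized, idx)
            k = spectral_gap_count(spectrum.eigenvalues)
            salient: list[str] = []
            for comp in range(k):
                for name in loading_gap_select(spectrum.eigenvectors[:, comp]):
                    if name not in salient:
                        salient.append(name)
            spectra.append(spectrum)
            dominant_counts.append(k)
            per_segment_salient.append(salient)
        salient_sets = aggregate_saliency(
            per_segment_salient, [s.label for s in self.segments]
        )
        return SaliencyResults(self, spectra, dominant_counts, salient_sets)


class SaliencyResults:
    """Fitted saliency analysis: spectra, dominant counts, salient sets."""

    def __init__(self, model, spectra, dominant_counts, salient_sets):
        self.model = model
        self.spectra: list[CovarianceSpectrum] = spectra
        self.dominant_counts: list[int] = dominant_counts
        self.salient_sets: dict[str, SalientSet] = salient_sets

    def to_json(self) -> str:
        return json.dumps(
            {
                label: {
                    "variables": s.variables,
                    "counts": s.counts,
                    "n_segments": len(s.per_segment),
                }
                for label, s in self.salient_sets.items()
            },
            indent=2,
        )

    def spectra_frame(self) -> pd.DataFrame:
        """Eigenvalue spectra, one row per segment (for gap plots)."""
        return pd.DataFrame(
            [s.eigenvalues for s in self.spectra],
            columns=[f"lambda_{i + 1}" for i in range(len(VARIABLE_NAMES))],
        )

    def summary(self) -> str:
        lines = ["Saliency analysis (spectral-gap PCA)", "=" * 40]
        values, counts = np.unique(self.dominant_counts, return_counts=True)
        tally = {int(v): int(c) for v, c in zip(values, counts)}
        lines.append(
            f"segments: {len(self.spectra)}; dominant components per segment: {tally}"
        )
        for label, s in self.salient_sets.items():
            lines.append(f"{label:>10}: {', '.join(s.variables)}")
        return "\n".join(lines)
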