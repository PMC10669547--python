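"""Corpus-level statistics: state summaries, B′ bands, PCA, KDE, mutant placement.

Everything here aggregates the per-chain outputs of
:mod:`pkalens.metrics` and :mod:`pkalens.bprime` across a corpus of
structures grouped by catalytic state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from sklearn.decomposition import PCA

from .bprime import BPrimeProfile
from .metrics import DistanceRecord, records_to_frame

__all__ = [
    "summarize",
    "state_profile",
    "PCAModel",
    "pca_profiles",
    "DensityModel",
    "kde_state",
    "MutantPlacement",
    "place_mutant",
]

_SUMMARY_ROWS = [
    "average", "median", "std_dev", "n",
    "min_value", "q1", "q2", "q3", "max_value",
]


def summarize(records: Iterable[DistanceRecord]) -> pd.DataFrame:
    """Per-(state, triplet, pair) distance summary table.

    For each cell: mean, median, sample standard deviation (0 for a
    single value), count of non-missing values, min, quartiles (linear
    interpolation between order statistics) and max. Missing distances
    are dropped per pair, so N may differ between the three pairs of
    one triplet within one state.
    """
    frame = records_to_frame(records).dropna(subset=["distance_angstrom"])

    def _cell(values: pd.Series) -> pd.Series:
        v = values.to_numpy()
        q1, q2, q3 = np.percentile(v, [25, 50, 75])
        return pd.Series(
            {
                "average": v.mean(),
                "median": float(np.median(v)),
                "std_dev": float(v.std(ddof=1)) if v.size > 1 else 0.0,
                "n": float(v.size),
                "min_value": float(v.min()),
                "q1": float(q1),
                "q2": float(q2),
                "q3": float(q3),
                "max_value": float(v.max()),
            }
        )

    if frame.empty:
        return pd.DataFrame(columns=_SUMMARY_ROWS)
    out = (
        frame.groupby(["state", "triplet", "pair"], sort=True, dropna=False)[
            "distance_angstrom"
        ]
        .apply(_cell)
        .unstack(-1)
        .reindex(columns=_SUMMARY_ROWS)
    )
    return out


def state_profile(
    profiles: Sequence[BPrimeProfile],
    ci: float = 0.95,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-residue mean B′ with a bootstrap confidence band for one state.

    The mean at each residue runs over the structures in which that
    residue is resolved. The confidence interval is a seeded percentile
    bootstrap over structures (default 1000 resamples); residues seen
    in fewer than two profiles keep their mean but get a missing CI.

    Returns a DataFrame indexed by (residue_seq, insertion_code) with
    columns ``mean``, ``ci_low``, ``ci_high``, ``n``.
    """
    if len(profiles) < 2:
        raise ValueError("state_profile requires at least two profiles")
    rng = np.random.default_rng(seed)
    alpha = (1.0 - ci) / 2.0

    by_residue: dict[tuple[int, str], list[float]] = {}
    for prof in profiles:
        for rid, val in prof.values.items():
            by_residue.setdefault((rid.residue_seq, rid.insertion_code), []).append(val)

    rows = {}
    for key in sorted(by_residue):
        vals = np.asarray(by_residue[key])
        n = vals.size
        mean = float(vals.mean())
        if n < 2:
            lo = hi = np.nan
        else:
            idx = rng.integers(0, n, size=(n_boot, n))
            boot_means = vals[idx].mean(axis=1)
            lo, hi = np.percentile(boot_means, [100 * alpha, 100 * (1 - alpha)])
        rows[key] = {"mean": mean, "ci_low": lo, "ci_high": hi, "n": n}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index = pd.MultiIndex.from_tuples(out.index, names=["residue_seq", "insertion_code"])
    return out


@dataclass
class PCAModel:
    """PCA of per-residue B′ profiles across structures.

    Rows of the input matrix are structures (first molecule of each),
    columns the residues resolved in every included profile. Columns
    are mean-centered but not variance-scaled — B′ values are already
    z-scored. ``loadings`` has shape (n_components, n_residues) and is
    row-orthonormal; signs are arbitrary.
    """

    structure_ids: list[str]
    residue_index: list[tuple[int, str]]
    loadings: np.ndarray
    explained_variance: np.ndarray  # fraction per component
    scores: np.ndarray  # (n_structures, n_components)

    def loadings_frame(self) -> pd.DataFrame:
        idx = pd.MultiIndex.from_tuples(
            self.residue_index, names=["residue_seq", "insertion_code"]
        )
        return pd.DataFrame(
            self.loadings.T,
            index=idx,
            columns=[f"PC{i+1}" for i in range(self.loadings.shape[0])],
        )

    def scores_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.scores,
            index=self.structure_ids,
            columns=[f"PC{i+1}" for i in range(self.scores.shape[1])],
        )


def pca_profiles(
    profiles: Sequence[BPrimeProfile],
    n_components: int = 3,
) -> PCAModel:
    """PCA over one B′ profile per structure (first chain per structure).

    When several profiles share a structure_id only the first one given
    is used — the convention for multi-copy asymmetric units is that
    the first molecule by chain name represents the structure. The
    residue set is the intersection of resolved residues across all
    included profiles; imputing unresolved residues would fabricate
    flexibility signal, so none is attempted.
    """
    chosen: dict[str, BPrimeProfile] = {}
    for prof in profiles:
        chosen.setdefault(prof.structure_id, prof)
    kept = list(chosen.values())
    if len(kept) < 3:
        raise ValueError("pca_profiles requires at least three structures")

    common: Optional[set] = None
    for prof in kept:
        keys = {(rid.residue_seq, rid.insertion_code) for rid in prof.values}
        common = keys if common is None else (common & keys)
    if not common:
        raise ValueError(
            "no residue is resolved in every profile; restrict the residue "
            "range or drop sparse structures"
        )
    residue_index = sorted(common)

    matrix = np.empty((len(kept), len(residue_index)))
    for i, prof in enumerate(kept):
        lookup = {
            (rid.residue_seq, rid.insertion_code): val for rid, val in prof.values.items()
        }
        matrix[i] = [lookup[key] for key in residue_index]

    n_components = min(n_components, len(kept) - 1, len(residue_index))
    pca = PCA(n_components=n_components, svd_solver="full")
    with np.errstate(invalid="ignore"):  # constant matrices: 0/0 ratio
        scores = pca.fit_transform(matrix)
    ratios = pca.explained_variance_ratio_
    if not np.all(np.isfinite(ratios)) or pca.explained_variance_.sum() < 1e-12:
        # numerically constant profiles: no variance to explain
        ratios = np.zeros_like(ratios)
    return PCAModel(
        structure_ids=[p.structure_id for p in kept],
        residue_index=residue_index,
        loadings=pca.components_.copy(),
        explained_variance=np.asarray(ratios, dtype=float),
        scores=scores,
    )


@dataclass
class DensityModel:
    """Gaussian KDE of one distance pair's distribution within one state."""

    pair: str
    state: str
    kde: gaussian_kde
    support: tuple[float, float]

    @property
    def bandwidth(self) -> float:
        """Kernel standard deviation in Å (Scott factor × data SD)."""
        return float(np.sqrt(self.kde.covariance[0, 0]))

    def evaluate(self, x: float | np.ndarray) -> np.ndarray:
        return self.kde(np.atleast_1d(np.asarray(x, dtype=float)))

    def peak(self, n_grid: int = 2048) -> float:
        """Distance (Å) at the density mode, located on a fine grid."""
        lo, hi = self.support
        grid = np.linspace(lo, hi, n_grid)
        return float(grid[np.argmax(self.kde(grid))])


def kde_state(
    values: Sequence[float] | np.ndarray,
    pair: str = "",
    state: str = "",
) -> DensityModel:
    """Gaussian kernel density (Scott's-rule bandwidth) of one distance set.

    Deterministic given the data. Requires at least two distinct
    values (a degenerate sample has no bandwidth).
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if np.unique(v).size < 2:
        raise ValueError("KDE requires at least two distinct values")
    kde = gaussian_kde(v, bw_method="scott")
    sd = float(np.sqrt(kde.covariance[0, 0]))
    support = (float(v.min() - 6 * sd), float(v.max() + 6 * sd))
    return DensityModel(pair=pair, state=state, kde=kde, support=support)


@dataclass
class MutantPlacement:
    """Where one structure's distance sits among the state densities."""

    distance: float
    density_per_state: dict[str, float]
    peak_per_state: dict[str, float]
    nearest_peak_state: str


def place_mutant(
    distance: Optional[float],
    densities: Mapping[str, DensityModel],
) -> Optional[MutantPlacement]:
    """Place one measured distance against per-state KDE densities.

    Reports each state's density at the distance and the state whose
    density peak lies nearest (purely descriptive — no significance
    claim). Returns ``None`` when the distance is missing. Peak ties
    break toward the alphabetically first state name for determinism.
    """
    if distance is None or not np.isfinite(distance):
        return None
    if len(densities) < 2:
        raise ValueError("need densities for at least two states")
    dens = {s: float(m.evaluate(distance)[0]) for s, m in sorted(densities.items())}
    peaks = {s: m.peak() for s, m in sorted(densities.items())}
    nearest = min(sorted(peaks), key=lambda s: (abs(peaks[s] - distance), s))
    return MutantPlacement(
        distance=float(distance),
        density_per_state=dens,
        peak_per_state=peaks,
        nearest_peak_state=nearest,
    )
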