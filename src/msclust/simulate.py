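"""Hierarchical Gaussian cluster simulator.

Samples are drawn from a zero-mean multivariate normal whose correlation
matrix encodes the clustering structure: unit variances, a block-constant
intra-cluster correlation for each inner block, a weaker constant
correlation tying inner blocks together into outer clusters (two-layer
scenarios), and zero correlation between outer clusters.  Independent
Gaussian noise of amplitude ``sigma`` is added entrywise, so the observable
intra-block correlation attenuates to ``rho / (1 + sigma**2)``.

Each *feature* (row) is one independent draw of the N-dimensional sample
vector; columns are the samples ("cells") that downstream similarity and
clustering operate on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "ScenarioSpec",
    "SimulatedDataset",
    "scenario_preset",
    "build_covariance",
    "simulate_dataset",
]

_CHOLESKY_JITTER = 1e-10


@dataclass(frozen=True)
class ScenarioSpec:
    """Parameters of one simulation scenario.

    ``inner_sizes`` are the sizes of the inner-layer blocks; ``outer_grouping``
    partitions inner-block indices into outer clusters (empty tuple for a
    single-layer scenario).  ``rho_in`` is the intra-inner-block correlation
    (rho1), ``rho_outer`` the correlation between samples sharing an outer
    cluster but not an inner block (rho2), and ``rho_between`` the remaining
    inter-cluster correlation (fixed at 0 in all scenarios).
    """

    scenario: str
    inner_sizes: tuple[int, ...]
    outer_grouping: tuple[tuple[int, ...], ...] = ()
    rho_in: float = 0.4
    rho_outer: float = 0.0
    rho_between: float = 0.0
    sigma: float = 1.0
    n_features: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in ("I", "II", "III"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if not self.inner_sizes:
            raise ValueError("inner_sizes must be nonempty")
        if any(s < 2 for s in self.inner_sizes):
            raise ValueError("all inner cluster sizes must be >= 2")
        if not (0.0 <= self.rho_in < 1.0):
            raise ValueError(f"rho_in={self.rho_in} outside [0, 1)")
        if not (0.0 <= self.rho_outer < 1.0):
            raise ValueError(f"rho_outer={self.rho_outer} outside [0, 1)")
        if self.rho_between != 0.0:
            raise ValueError("rho_between is fixed at 0 in all scenarios")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.n_features < 2:
            raise ValueError("n_features must be >= 2 (correlations undefined otherwise)")
        if self.outer_grouping:
            if self.rho_in <= self.rho_outer:
                raise ValueError(
                    f"two-layer scenario requires rho_in > rho_outer "
                    f"(got rho_in={self.rho_in}, rho_outer={self.rho_outer})"
                )
            flat = [i for grp in self.outer_grouping for i in grp]
            if sorted(flat) != list(range(len(self.inner_sizes))):
                raise ValueError("outer_grouping must partition the inner block indices")
        elif self.rho_outer != 0.0:
            raise ValueError("rho_outer must be 0 for single-layer scenarios")

    @property
    def n_samples(self) -> int:
        return int(sum(self.inner_sizes))


@dataclass
class SimulatedDataset:
    """A drawn dataset: ``data`` is n_features x n_samples (rows = features)."""

    data: np.ndarray
    labels_inner: np.ndarray
    labels_outer: Optional[np.ndarray]
    sample_ids: list[str]
    spec: ScenarioSpec

    def inner_clusters(self) -> dict[str, set[str]]:
        """Ground-truth inner-layer clusters as name -> set of sample ids."""
        return _label_sets(self.labels_inner, self.sample_ids)

    def outer_clusters(self) -> dict[str, set[str]]:
        if self.labels_outer is None:
            raise ValueError("scenario has no outer layer")
        return _label_sets(self.labels_outer, self.sample_ids)


def _label_sets(labels: np.ndarray, ids: Sequence[str]) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    for cid, lab in zip(ids, labels):
        out.setdefault(str(lab), set()).add(cid)
    return out


#: scenario I inner-block sizes: 12 clusters of 25, 6 of 50, 3 of 100.
SCENARIO_I_SIZES: tuple[int, ...] = (25,) * 12 + (50,) * 6 + (100,) * 3


def _contiguous_grouping(sizes: Sequence[int]) -> tuple[tuple[int, ...], ...]:
    """Adjoin consecutive inner blocks into groups of the given counts."""
    groups = []
    start = 0
    for n in sizes:
        groups.append(tuple(range(start, start + n)))
        start += n
    return tuple(groups)


def scenario_preset(
    scenario: str,
    rho_in: Optional[float] = None,
    delta_rho: float = 0.125,
    sigma: float = 1.0,
    n_features: int = 500,
    seed: int = 0,
) -> ScenarioSpec:
    """Build a ScenarioSpec with the canonical block layouts.

    Scenario I: single layer, irregular sizes (12x25, 6x50, 3x100).
    Scenario II: 21 inner blocks of 50, adjoined contiguously into 6 outer
    clusters (groups of 4,4,4,3,3,3 blocks); rho_in defaults to 2*delta_rho
    so that (rho1, rho2) = (0.25, 0.125) at the canonical delta_rho = 0.125.
    Scenario III: scenario-I inner sizes, outer clusters formed by merging
    4 size-25 blocks, 2 size-50 blocks, or 1 size-100 block (9 outer
    clusters of 100 samples each).
    """
    scenario = scenario.upper()
    if scenario == "I":
        return ScenarioSpec(
            scenario="I",
            inner_sizes=SCENARIO_I_SIZES,
            rho_in=0.4 if rho_in is None else rho_in,
            sigma=sigma,
            n_features=n_features,
            seed=seed,
        )
    if rho_in is None:
        rho_in = 2.0 * delta_rho
    rho_outer = rho_in - delta_rho
    if scenario == "II":
        return ScenarioSpec(
            scenario="II",
            inner_sizes=(50,) * 21,
            outer_grouping=_contiguous_grouping((4, 4, 4, 3, 3, 3)),
            rho_in=rho_in,
            rho_outer=rho_outer,
            sigma=sigma,
            n_features=n_features,
            seed=seed,
        )
    if scenario == "III":
        # 12 size-25 blocks in groups of 4, 6 size-50 in pairs, 3 size-100 alone
        grouping = (
            (0, 1, 2, 3), (4, 5, 6, 7), (8, 9, 10, 11),
            (12, 13), (14, 15), (16, 17),
            (18,), (19,), (20,),
        )
        return ScenarioSpec(
            scenario="III",
            inner_sizes=SCENARIO_I_SIZES,
            outer_grouping=grouping,
            rho_in=rho_in,
            rho_outer=rho_outer,
            sigma=sigma,
            n_features=n_features,
            seed=seed,
        )
    raise ValueError(f"unknown scenario {scenario!r}")


def build_covariance(spec: ScenarioSpec) -> np.ndarray:
    """Block-constant correlation matrix for the scenario.

    Unit diagonal; ``rho_in`` within inner blocks; ``rho_outer`` between
    samples sharing an outer cluster but not an inner block; 0 elsewhere.
    Raises if the configuration is not positive semi-definite.
    """
    n = spec.n_samples
    sigma_mat = np.full((n, n), spec.rho_between, dtype=float)

    offsets = np.concatenate([[0], np.cumsum(spec.inner_sizes)])
    if spec.outer_grouping:
        for grp in spec.outer_grouping:
            idx = np.concatenate([np.arange(offsets[b], offsets[b + 1]) for b in grp])
            sigma_mat[np.ix_(idx, idx)] = spec.rho_outer
    for b in range(len(spec.inner_sizes)):
        lo, hi = offsets[b], offsets[b + 1]
        sigma_mat[lo:hi, lo:hi] = spec.rho_in
    np.fill_diagonal(sigma_mat, 1.0)

    _cholesky_with_jitter(sigma_mat, spec)  # PSD validation
    return sigma_mat


def _cholesky_with_jitter(sigma_mat: np.ndarray, spec: ScenarioSpec) -> np.ndarray:
    try:
        return np.linalg.cholesky(sigma_mat)
    except np.linalg.LinAlgError:
        pass
    try:
        n = sigma_mat.shape[0]
        return np.linalg.cholesky(sigma_mat + _CHOLESKY_JITTER * np.eye(n))
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            f"covariance not positive semi-definite for rho_in={spec.rho_in}, "
            f"rho_outer={spec.rho_outer}, sizes={spec.inner_sizes}"
        ) from exc


def simulate_dataset(spec: ScenarioSpec) -> SimulatedDataset:
    """Draw ``spec.n_features`` independent rows of X' = X + eps.

    X ~ N(0, Sigma) with Sigma from :func:`build_covariance`; eps is i.i.d.
    N(0, sigma^2) per entry.  Deterministic for a given ``spec.seed``.
    """
    sigma_mat = build_covariance(spec)
    chol = _cholesky_with_jitter(sigma_mat, spec)
    n = spec.n_samples
    rng = np.random.default_rng(spec.seed)
    data = rng.standard_normal((spec.n_features, n)) @ chol.T
    if spec.sigma > 0:
        data = data + spec.sigma * rng.standard_normal(data.shape)

    labels_inner = np.concatenate(
        [np.full(sz, f"in{b + 1:02d}") for b, sz in enumerate(spec.inner_sizes)]
    )
    labels_outer = None
    if spec.outer_grouping:
        block_to_outer = {}
        for o, grp in enumerate(spec.outer_grouping):
            for b in grp:
                block_to_outer[b] = f"out{o + 1:02d}"
        labels_outer = np.concatenate(
            [np.full(sz, block_to_outer[b]) for b, sz in enumerate(spec.inner_sizes)]
        )
    width = len(str(n))
    sample_ids = [f"S{i + 1:0{width}d}" for i in range(n)]
    return SimulatedDataset(
        data=data,
        labels_inner=labels_inner,
        labels_outer=labels_outer,
        sample_ids=sample_ids,
        spec=spec,
    )
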