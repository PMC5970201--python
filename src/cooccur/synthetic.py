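"""Synthetic OTU tables with planted basis correlation structure.

The generator emulates the data-generating process the compositional
correlation model assumes: latent log-normal basis abundances with a chosen
correlation matrix, closed to fractions per sample, then observed through
multinomial sequencing noise at a heterogeneous depth.  Because the planted
correlations live on the log-basis scale — the scale the estimator targets —
every pipeline stage can be checked against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .otu_table import OTUTable

__all__ = [
    "SyntheticSpec",
    "SyntheticTruth",
    "build_correlation_matrix",
    "generate_table",
    "null_scenario",
    "planted_pair_scenario",
    "kakapo_like_scenario",
    "fixture_graphs",
]

MIN_EIGENVALUE = 1e-8


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic community.

    ``planted_correlations`` lists pairwise targets (i, j, r); ``blocks``
    lists (member_indices, within_block_r) equicorrelated groups.  The
    resulting target matrix must be positive definite.
    ``target_shares`` maps OTU index to a desired global read share; the
    OTU's log-mean is calibrated so its expected share matches.
    """

    n_otus: int
    n_samples: int
    depth_range: tuple[int, int]
    log_mean: np.ndarray | None = None
    log_sd: np.ndarray | None = None
    planted_correlations: list[tuple[int, int, float]] = field(default_factory=list)
    blocks: list[tuple[list[int], float]] = field(default_factory=list)
    dominant_otu_share: float | None = None
    target_shares: dict[int, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_otus < 2 or self.n_samples < 1:
            raise ValueError("need at least 2 OTUs and 1 sample")
        lo, hi = self.depth_range
        if lo < 1 or hi < lo:
            raise ValueError("depth_range must satisfy 1 <= min <= max")
        self.log_mean = (
            np.zeros(self.n_otus) if self.log_mean is None else np.asarray(self.log_mean, float)
        )
        self.log_sd = (
            np.ones(self.n_otus) if self.log_sd is None else np.asarray(self.log_sd, float)
        )
        if self.log_mean.shape != (self.n_otus,) or self.log_sd.shape != (self.n_otus,):
            raise ValueError("log_mean / log_sd must have length n_otus")
        if (self.log_sd < 0).any():
            raise ValueError("log_sd must be non-negative")
        if self.dominant_otu_share is not None and 0 not in self.target_shares:
            self.target_shares = {0: float(self.dominant_otu_share), **self.target_shares}

    def to_dict(self) -> dict:
        return {
            "n_otus": self.n_otus,
            "n_samples": self.n_samples,
            "depth_range": list(self.depth_range),
            "log_mean": self.log_mean.tolist(),
            "log_sd": self.log_sd.tolist(),
            "planted_correlations": [list(p) for p in self.planted_correlations],
            "blocks": [[list(m), r] for m, r in self.blocks],
            "dominant_otu_share": self.dominant_otu_share,
            "target_shares": {str(k): v for k, v in self.target_shares.items()},
            "seed": self.seed,
        }


@dataclass
class SyntheticTruth:
    """A generated table paired with the basis correlation matrix that made it."""

    spec: SyntheticSpec
    basis_correlation: np.ndarray
    table: OTUTable
    log_basis: np.ndarray | None = None  # latent log abundances (otu x sample)


def build_correlation_matrix(spec: SyntheticSpec) -> np.ndarray:
    """Identity plus planted entries, validated positive definite."""
    d = spec.n_otus
    corr = np.eye(d)
    entries: dict[tuple[int, int], float] = {}

    def put(i: int, j: int, r: float) -> None:
        if i == j:
            raise ValueError("cannot plant a correlation of an OTU with itself")
        if not (-1.0 < r < 1.0):
            raise ValueError(f"planted correlation must lie in (-1, 1), got {r}")
        key = tuple(sorted((i, j)))
        if key in entries and not np.isclose(entries[key], r):
            raise ValueError(f"conflicting planted correlations for pair {key}")
        entries[key] = r

    for i, j, r in spec.planted_correlations:
        put(int(i), int(j), float(r))
    for members, r in spec.blocks:
        members = [int(m) for m in members]
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                put(members[a], members[b], float(r))
    for (i, j), r in entries.items():
        if not (0 <= i < d and 0 <= j < d):
            raise ValueError(f"planted index out of range: {(i, j)}")
        corr[i, j] = corr[j, i] = r

    smallest = float(np.linalg.eigvalsh(corr)[0])
    if smallest <= MIN_EIGENVALUE:
        raise ValueError(
            f"planted correlation matrix is not positive definite "
            f"(smallest eigenvalue {smallest:.3g}); weaken r or shrink blocks"
        )
    return corr


def _expected_share(log_mean, log_sd, sqrt_cov, target_otu, rng, n_draws=2000):
    """Monte Carlo estimate of one OTU's expected relative abundance."""
    z = rng.standard_normal((len(log_mean), n_draws))
    log_x = log_mean[:, None] + sqrt_cov @ z
    log_x -= log_x.max(axis=0, keepdims=True)  # overflow guard
    x = np.exp(log_x)
    fractions = x / x.sum(axis=0, keepdims=True)
    return float(fractions[target_otu].mean())


def _calibrate_log_means(spec: SyntheticSpec, sqrt_cov: np.ndarray) -> np.ndarray:
    """Bisect per-OTU log-mean offsets so expected shares hit their targets.

    Targets are adjusted one at a time in a few fixed-point sweeps; shares
    interact through the closure, so a couple of rounds suffice for the mild
    targets used here.
    """
    log_mean = spec.log_mean.copy()
    if not spec.target_shares:
        return log_mean
    cal_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xCA11B]))
    for _ in range(3):  # fixed-point sweeps over the (few) targeted OTUs
        for otu, target in spec.target_shares.items():
            lo, hi = -20.0, 20.0
            base = log_mean[otu]
            for _ in range(24):
                mid = (lo + hi) / 2.0
                log_mean[otu] = base + mid
                share = _expected_share(log_mean, spec.log_sd, sqrt_cov, otu, cal_rng)
                if share < target:
                    lo = mid
                else:
                    hi = mid
            log_mean[otu] = base + (lo + hi) / 2.0
    return log_mean


def generate_table(spec: SyntheticSpec) -> SyntheticTruth:
    """Draw a count table from the log-normal-multinomial generator.

    Per sample: log-basis abundances ~ MVN(log_mean, diag(sd)·C·diag(sd))
    via the symmetric spectral square root (deterministic given the seed),
    closed to fractions, then counts ~ Multinomial(depth, fractions) with
    depth uniform over ``depth_range``.
    """
    corr = build_correlation_matrix(spec)
    cov = np.outer(spec.log_sd, spec.log_sd) * corr
    eigval, eigvec = np.linalg.eigh(cov)
    sqrt_cov = eigvec @ np.diag(np.sqrt(np.clip(eigval, 0.0, None))) @ eigvec.T

    log_mean = _calibrate_log_means(spec, sqrt_cov)

    rng = np.random.default_rng(spec.seed)
    d, n = spec.n_otus, spec.n_samples
    z = rng.standard_normal((d, n))
    log_basis = log_mean[:, None] + sqrt_cov @ z
    log_x = log_basis - log_basis.max(axis=0, keepdims=True)  # overflow guard
    x = np.exp(log_x)
    fractions = x / x.sum(axis=0, keepdims=True)

    lo, hi = spec.depth_range
    depths = rng.integers(lo, hi + 1, size=n)
    counts = np.empty((d, n), dtype=np.int64)
    for j in range(n):
        counts[:, j] = rng.multinomial(depths[j], fractions[:, j])

    width = max(2, len(str(d)))
    otu_ids = [f"OTU_{i:0{width}d}" for i in range(1, d + 1)]
    sample_ids = [f"S{j:02d}" for j in range(1, n + 1)]
    table = OTUTable(otu_ids, sample_ids, counts)
    return SyntheticTruth(spec, corr, table, log_basis)


def null_scenario(n_otus: int = 30, n_samples: int = 50, depth: int = 2000, seed: int = 0) -> SyntheticTruth:
    """Independent OTUs (identity basis correlation): the type-I error harness."""
    spec = SyntheticSpec(
        n_otus=n_otus,
        n_samples=n_samples,
        depth_range=(depth, depth),
        seed=seed,
    )
    return generate_table(spec)


def planted_pair_scenario(
    r: float = 0.8,
    n_otus: int = 30,
    n_samples: int = 50,
    depth: int = 2000,
    seed: int = 0,
) -> SyntheticTruth:
    """One correlated pair (OTUs 0 and 1) among otherwise independent OTUs."""
    spec = SyntheticSpec(
        n_otus=n_otus,
        n_samples=n_samples,
        depth_range=(depth, depth),
        planted_correlations=[(0, 1, r)],
        seed=seed,
    )
    return generate_table(spec)


def kakapo_like_scenario(seed: int = 0) -> SyntheticTruth:
    """A community shaped like the kakapo hindgut study.

    42 samples, 60 OTUs, depths 2,000–10,000; OTU_01 dominant (~30% of reads,
    uncorrelated with everything, mirroring the isolate dominant node); OTU_02
    (~20% of reads) positively correlated (r = 0.6) with one partner; and two
    small equicorrelated blocks (r = 0.75) among minority OTUs.  Abundance
    falls off geometrically into a rare tail, so the prevalence filter has
    something to remove.
    """
    d = 60
    log_mean = np.linspace(2.0, -16.0, d)  # geometric fall-off into a rare tail
    spec = SyntheticSpec(
        n_otus=d,
        n_samples=42,
        depth_range=(2000, 10000),
        log_mean=log_mean,
        log_sd=np.ones(d),
        planted_correlations=[(1, 2, 0.6)],
        blocks=[([3, 4, 5, 6, 7], 0.75), ([8, 9, 10, 11, 12], 0.75)],
        target_shares={0: 0.30, 1: 0.20},
        seed=seed,
    )
    return generate_table(spec)


def fixture_graphs() -> dict[str, nx.Graph]:
    """Deterministic small graphs used as fixtures across the test suite."""
    graphs: dict[str, nx.Graph] = {}
    graphs["triangle"] = nx.complete_graph(3)
    graphs["path3"] = nx.path_graph(3)
    graphs["star5"] = nx.star_graph(4)  # center + 4 leaves = 5 nodes
    graphs["K4"] = nx.complete_graph(4)
    k4_minus = nx.complete_graph(4)
    k4_minus.remove_edge(0, 1)
    graphs["K4_minus_edge"] = k4_minus
    tri5 = nx.Graph()
    for b in range(5):
        base = 3 * b
        tri5.add_edges_from([(base, base + 1), (base + 1, base + 2), (base, base + 2)])
    graphs["triangles_x5"] = tri5
    graphs["edgeless_10"] = nx.empty_graph(10)
    return graphs
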