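"""Synthetic landscapes, spatial effects, occurrences and haplotype alignments.

Every generator is a pure function of its arguments and an explicit integer
seed, so downstream stages (collinearity screening, the iCAR occupancy fit,
projection, dispersal, haplotype summaries) can be exercised end to end with
known ground truth and no external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .landscape import CovariateStack, NeighborGraph
from .popgen import Alignment

__all__ = [
    "LandscapeSpec",
    "TruthRecord",
    "make_landscape",
    "simulate_spatial_effect",
    "simulate_occurrences",
    "make_truth",
    "make_haplotype_alignment",
    "study_like_alignment",
]


@dataclass(frozen=True)
class LandscapeSpec:
    """Parameters of a synthetic covariate stack.

    ``autocorr_range`` is the e-folding range of spatial autocorrelation in
    cell units (the layers are Gaussian-smoothed white noise with that
    kernel width); ``cell_size_deg`` georeferences the grid.
    """

    n_rows: int
    n_cols: int
    n_covariates: int
    autocorr_range: float = 3.0
    cell_size_deg: float = 1.0 / 24.0  # 2.5 arc-minutes
    origin_lon: float = -72.0
    origin_lat: float = -25.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0 or self.n_covariates <= 0:
            raise ValueError("n_rows, n_cols and n_covariates must be positive")
        if self.n_rows * self.n_cols < 4:
            raise ValueError("grid must have at least 4 cells")
        if self.autocorr_range <= 0:
            raise ValueError("autocorr_range must be > 0")
        if self.autocorr_range >= max(self.n_rows, self.n_cols):
            raise ValueError("autocorr_range must be smaller than the grid extent")
        if self.cell_size_deg <= 0:
            raise ValueError("cell_size_deg must be > 0")


@dataclass
class TruthRecord:
    """Ground truth for a simulated occupancy surface.

    ``pi`` is the per-cell presence probability, inverse-logit(X beta + rho),
    with ``rho`` a sum-to-zero intrinsic-CAR draw of variance ``v_rho``.
    """

    beta: np.ndarray  # fixed effects, intercept first
    v_rho: float
    rho: np.ndarray  # per valid cell
    pi: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.rho = np.asarray(self.rho, dtype=float)
        if self.v_rho <= 0:
            raise ValueError("v_rho must be > 0")
        if abs(self.rho.sum()) > 1e-6 * max(1, self.rho.size):
            raise ValueError("rho must sum to zero")


def make_landscape(spec: LandscapeSpec) -> CovariateStack:
    """Generate spatially autocorrelated, standardized covariate layers.

    Each layer is white noise smoothed with a Gaussian kernel of width
    ``autocorr_range`` cells, then standardized to mean 0 / sd 1 over valid
    cells. Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    layers = []
    for _ in range(spec.n_covariates):
        z = rng.standard_normal((spec.n_rows, spec.n_cols))
        z = gaussian_filter(z, sigma=spec.autocorr_range, mode="reflect")
        z = (z - z.mean()) / z.std()
        layers.append(z)
    names = [f"x{i + 1}" for i in range(spec.n_covariates)]
    return CovariateStack(
        np.stack(layers), names, spec.cell_size_deg, spec.origin_lon, spec.origin_lat
    )


def simulate_spatial_effect(graph: NeighborGraph, v_rho: float, seed: int) -> np.ndarray:
    """One draw from the intrinsic CAR prior on a connected cell graph.

    The iCAR is an improper Gaussian Markov random field with precision
    L / v_rho (L the graph Laplacian); conditionally each cell is normal
    around its neighbor mean with variance v_rho / n_j. The draw is taken on
    the proper subspace orthogonal to the null eigenvector (constant vector)
    via the Laplacian eigendecomposition, then centered so it sums to zero.
    """
    if v_rho <= 0:
        raise ValueError("v_rho must be > 0")
    from .landscape import _components

    n_comp, labels = _components(graph)
    if n_comp > 1:
        sizes = np.bincount(labels).tolist()
        raise ValueError(f"graph is disconnected ({n_comp} components, sizes {sizes})")
    if graph.n == 1:
        return np.zeros(1)
    lam, vec = np.linalg.eigh(graph.laplacian().toarray())
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(graph.n)
    # eigenvalue 0 (constant mode) carries no mass
    scale = np.where(lam > 1e-10, np.sqrt(v_rho / np.where(lam > 1e-10, lam, 1.0)), 0.0)
    rho = vec @ (scale * z)
    rho -= rho.mean()
    return rho


def make_truth(
    stack: CovariateStack,
    graph: NeighborGraph,
    beta: np.ndarray,
    v_rho: float,
    seed: int,
) -> TruthRecord:
    """Assemble a TruthRecord: draw rho, compute pi = expit(X beta + rho)."""
    beta = np.asarray(beta, dtype=float)
    X = stack.design_matrix(intercept=True)
    if X.shape[1] != beta.size:
        raise ValueError(f"beta has {beta.size} entries but design has {X.shape[1]} columns")
    rho = simulate_spatial_effect(graph, v_rho, seed)
    pi = expit(X @ beta + rho)
    return TruthRecord(beta=beta, v_rho=v_rho, rho=rho, pi=pi)


def simulate_occurrences(stack: CovariateStack, truth: TruthRecord, seed: int) -> pd.DataFrame:
    """Per-cell Bernoulli presence/absence draws at the truth probabilities.

    Returns a DataFrame with columns lon, lat, presence (0/1) and source,
    one record per valid cell (cell-center coordinates), deterministic given
    ``seed``.
    """
    pi = np.asarray(truth.pi, dtype=float)
    if pi.size != stack.n_valid:
        raise ValueError("truth.pi must be defined on every valid cell")
    if np.any((pi < 0) | (pi > 1)):
        raise ValueError("presence probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    y = (rng.random(pi.size) < pi).astype(int)
    lon, lat = stack.valid_cell_centers()
    return pd.DataFrame(
        {"lon": lon, "lat": lat, "presence": y, "source": "synthetic"}
    )


# ---------------------------------------------------------------------------
# haplotype alignments

_BASES = "ACGT"


def make_haplotype_alignment(
    n_seqs: int,
    length: int,
    hap_defs: list[tuple[dict[int, str], int]],
    seed: int = 0,
    ref: str | None = None,
) -> Alignment:
    """Build an alignment with known haplotype structure.

    ``hap_defs`` is a list of (mutations, count) pairs where ``mutations``
    maps site position -> base, applied to a common reference sequence
    (random at ``seed`` unless ``ref`` is given). True values of the number
    of segregating sites, haplotype counts and nucleotide diversity follow
    directly from the definitions.
    """
    counts = [c for _, c in hap_defs]
    if sum(counts) != n_seqs:
        raise ValueError(f"haplotype counts sum to {sum(counts)}, expected {n_seqs}")
    for muts, _ in hap_defs:
        for pos in muts:
            if not 0 <= pos < length:
                raise ValueError(f"mutated site {pos} outside [0, {length})")
    keys = [tuple(sorted(m.items())) for m, _ in hap_defs]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate haplotype definitions")

    rng = np.random.default_rng(seed)
    if ref is None:
        ref = "".join(rng.choice(list(_BASES), size=length))
    elif len(ref) != length:
        raise ValueError("reference length mismatch")

    seqs: list[tuple[str, str]] = []
    k = 0
    for h, (muts, count) in enumerate(hap_defs):
        s = list(ref)
        for pos, base in muts.items():
            if s[pos] == base:
                raise ValueError(f"haplotype {h}: site {pos} already has state {base}")
            s[pos] = base
        hap_seq = "".join(s)
        for _ in range(count):
            seqs.append((f"hap{h + 1}_{k + 1}", hap_seq))
            k += 1
    return Alignment(seqs)


def study_like_alignment(seed: int = 0) -> Alignment:
    """A 14-sequence, 955-bp fixture emulating the structure of a small
    mitochondrial ND1 survey: 4 haplotypes in counts (5, 5, 3, 1), defined by
    17 polymorphic sites arranged in three divergent clades (two close
    haplotypes, one moderately and one strongly diverged).

    Synthetic stand-in: sequence content is random apart from the engineered
    variant sites; only the summary statistics (S, haplotype counts, H and
    its sampling variance) mirror the real survey.
    """
    rng = np.random.default_rng(seed)
    length = 955
    ref = "".join(rng.choice(list(_BASES), size=length))
    sites = rng.choice(length, size=17, replace=False)
    sites.sort()

    def mut(positions: np.ndarray) -> dict[int, str]:
        out = {}
        for p in positions:
            alts = [b for b in _BASES if b != ref[p]]
            out[int(p)] = alts[int(rng.integers(3))]
        return out

    # hap1 = reference; hap2 carries sites 0-7; hap3 = hap2 plus site 8;
    # hap4 carries sites 9-16 (its own clade)
    m2 = mut(sites[0:8])
    m3 = {**m2, **mut(sites[8:9])}
    m4 = mut(sites[9:17])
    hap_defs = [({}, 5), (m2, 5), (m3, 3), (m4, 1)]
    return make_haplotype_alignment(14, length, hap_defs, seed=seed, ref=ref)
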