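"""Frequency-domain source estimation and source-level statistics.

Pipeline: reduce each source's three gain columns to its two dominant
orientations by SVD, depth-weight, solve the minimum L1-norm cone
program at the complex sensor Fourier coefficients of one frequency
bin, summarize each source by the RMS of the four real coefficients,
contrast against the average of the two neighbouring bins, smooth on
the source grid, log-transform, and test voxelwise with a one-tailed
paired t and sign-flip cluster-level FWE correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .errors import ConfigError, DegenerateSourceError, InvalidGeometryError
from .grids import Leadfield, SourceGrid
from .socp import GroupL1Solution, group_norms, solve_group_l1
from .spectral import EvokedResponse, bin_index

__all__ = [
    "ReducedLeadfield",
    "FrequencyBin",
    "SourceSolution",
    "ActivationMap",
    "ClusterResult",
    "reduce_orientations",
    "depth_weights",
    "erf_frequency_bin",
    "solve_l1_bin",
    "rms_activation",
    "neighbor_control_map",
    "smooth_and_log",
    "voxelwise_cluster_test",
    "roi_extract",
]


@dataclass(frozen=True)
class ReducedLeadfield:
    """Gain reduced to two dominant orientations per source.

    ``gain2`` is m x (n*2) with columns (theta_i, phi_i) per source;
    ``orientations`` is (n, 2, 3) orthonormal pairs; ``depth_weights``
    is the length-n positive weight vector w; ``discarded_energy`` is
    the per-source fraction of squared gain lost in the reduction.
    """

    gain2: np.ndarray
    orientations: np.ndarray
    depth_weights: np.ndarray
    grid: SourceGrid
    discarded_energy: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def n_sensors(self) -> int:
        return self.gain2.shape[0]

    @property
    def n_sources(self) -> int:
        return self.gain2.shape[1] // 2

    def with_weights(self, w: np.ndarray) -> "ReducedLeadfield":
        w = np.asarray(w, dtype=float)
        if w.shape != (self.n_sources,) or np.any(w <= 0):
            raise ConfigError("depth weights must be positive, one per source")
        return ReducedLeadfield(
            gain2=self.gain2,
            orientations=self.orientations,
            depth_weights=w,
            grid=self.grid,
            discarded_energy=self.discarded_energy,
        )


@dataclass(frozen=True)
class FrequencyBin:
    """Complex sensor Fourier coefficients at one bin."""

    data: np.ndarray
    freq: float

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=complex).ravel()
        if not np.all(np.isfinite(d)):
            raise ConfigError("frequency-bin data must be finite")
        object.__setattr__(self, "data", d)


@dataclass(frozen=True)
class SourceSolution:
    """Per-source complex orientation pair plus solver diagnostics.

    ``omega`` is (n, 2) complex: columns are the theta and phi
    orientation coefficients.  The objective is the depth-weighted sum
    of per-source norms over the four real components, evaluated on
    ``omega`` exactly.
    """

    omega: np.ndarray
    freq: float
    objective: float
    residual_norm: float
    weights: np.ndarray
    n_iter: int = 0

    @property
    def n_sources(self) -> int:
        return self.omega.shape[0]

    def stacked_real(self) -> np.ndarray:
        """(n*4,) layout: (re_theta, im_theta, re_phi, im_phi) per source."""
        o = self.omega
        return np.column_stack(
            [o[:, 0].real, o[:, 0].imag, o[:, 1].real, o[:, 1].imag]
        ).ravel()


@dataclass(frozen=True)
class ActivationMap:
    """Scalar activation per grid point at one frequency bin."""

    values: np.ndarray
    grid: SourceGrid
    freq: float = np.nan
    condition: str = ""
    log_transformed: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float).ravel()
        if v.shape[0] != self.grid.n_sources:
            raise ConfigError("activation length must match the grid")
        if not self.log_transformed and np.any(v < 0):
            raise ConfigError("activation values must be nonnegative before log")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class ClusterResult:
    """Cluster-corrected voxelwise test outcome."""

    voxel_t: np.ndarray
    df: int
    t_threshold: float
    clusters: list[dict]  # {"voxels", "peak", "peak_t", "mass", "p"}

    @property
    def significant(self) -> list[dict]:
        return [c for c in self.clusters if c["significant"]]


def reduce_orientations(lf: Leadfield) -> ReducedLeadfield:
    """SVD each source's m x 3 block onto its two dominant orientations.

    theta and phi are the right singular vectors of the two largest
    singular values; the reduced columns are the block projected onto
    them.  Sign convention for determinism: each singular vector is
    flipped so its largest-magnitude component is positive.
    """
    m, n = lf.n_sensors, lf.n_sources
    gain2 = np.empty((m, 2 * n))
    orientations = np.empty((n, 2, 3))
    discarded = np.empty(n)
    for i in range(n):
        blk = lf.block(i)
        if not np.any(blk):
            raise DegenerateSourceError(f"source {i} has an all-zero gain block")
        u, s, vt = np.linalg.svd(blk, full_matrices=False)
        for k in range(2):
            v = vt[k]
            j = int(np.argmax(np.abs(v)))
            if v[j] < 0:
                v = -v
            orientations[i, k] = v
            gain2[:, 2 * i + k] = blk @ v
        total = float(np.sum(s**2))
        discarded[i] = float(s[2] ** 2 / total) if len(s) > 2 else 0.0
    return ReducedLeadfield(
        gain2=gain2,
        orientations=orientations,
        depth_weights=np.ones(n),
        grid=lf.grid,
        discarded_energy=discarded,
    )


def depth_weights(lf: Leadfield, gamma: float = 1.0) -> np.ndarray:
    """Depth weights w_i = ||G_i||_F^gamma, normalized to mean 1.

    gamma = 0 gives uniform weights; gamma = 1 (default) penalizes
    superficial high-gain sources in proportion to their gain norm,
    counteracting the superficial bias of minimum-norm solutions.
    """
    if gamma < 0:
        raise ConfigError("gamma must be >= 0")
    norms = np.array([np.linalg.norm(lf.block(i)) for i in range(lf.n_sources)])
    if np.any(norms == 0):
        raise DegenerateSourceError("zero-norm gain block")
    w = norms**gamma
    return w / w.mean()


def erf_frequency_bin(erf: EvokedResponse, f: float) -> FrequencyBin:
    """Complex sensor Fourier coefficients of the evoked window at ``f``.

    Coefficients follow the same 1/sqrt(N) scaling as the power
    convention (|K_f|^2 equals the spectral power at the bin).
    """
    n = erf.data.shape[1]
    coefs = np.fft.rfft(erf.data, axis=-1) / np.sqrt(n)
    freqs = np.fft.rfftfreq(n, 1.0 / erf.sfreq)
    i = bin_index(freqs, f)
    return FrequencyBin(data=coefs[:, i], freq=float(freqs[i]))


def _constraint_matrix(rlf: ReducedLeadfield) -> np.ndarray:
    """Real expansion of K_f = G Omega_f.

    Rows: [Re(K); Im(K)].  Columns per source: (re_theta, im_theta,
    re_phi, im_phi) — the real and imaginary constraint blocks share
    the same gain columns.
    """
    m, n = rlf.n_sensors, rlf.n_sources
    A = np.zeros((2 * m, 4 * n))
    for i in range(n):
        gt = rlf.gain2[:, 2 * i]
        gp = rlf.gain2[:, 2 * i + 1]
        A[:m, 4 * i + 0] = gt
        A[m:, 4 * i + 1] = gt
        A[:m, 4 * i + 2] = gp
        A[m:, 4 * i + 3] = gp
    return A


def solve_l1_bin(
    kf: FrequencyBin,
    rlf: ReducedLeadfield,
    noise_tol: float | None = None,
    **solver_kwargs,
) -> SourceSolution:
    """Minimum L1-norm estimate at one frequency bin.

    The complex equality ``K_f = G Omega_f`` is split into real and
    imaginary linear constraints sharing Omega's real and imaginary
    parts; the objective is the depth-weighted sum of per-source
    Euclidean norms over the four real components.  ``noise_tol``
    switches to the relaxed ball constraint ``||K_f - G Omega|| <=
    noise_tol``.
    """
    if kf.data.shape[0] != rlf.n_sensors:
        raise ConfigError("frequency-bin length does not match the leadfield")
    A = _constraint_matrix(rlf)
    b = np.concatenate([kf.data.real, kf.data.imag])
    sol = solve_group_l1(
        A, b, rlf.depth_weights, group_size=4, noise_tol=noise_tol, **solver_kwargs
    )
    blocks = sol.x.reshape(-1, 4)
    omega = np.column_stack(
        [blocks[:, 0] + 1j * blocks[:, 1], blocks[:, 2] + 1j * blocks[:, 3]]
    )
    return SourceSolution(
        omega=omega,
        freq=kf.freq,
        objective=sol.objective,
        residual_norm=sol.residual_norm,
        weights=rlf.depth_weights,
        n_iter=sol.n_iter,
    )


def rms_activation(sol: SourceSolution, grid: SourceGrid, condition: str = "") -> ActivationMap:
    """RMS over the four real components per source.

    value_i = sqrt((re_t^2 + im_t^2 + re_p^2 + im_p^2) / 4), i.e. the
    per-source group norm divided by 2.  The denominator convention (4
    real components) is a fixed documented choice; any alternative is a
    constant factor that cancels in all contrasts.
    """
    gn = group_norms(sol.stacked_real(), 4)
    return ActivationMap(values=gn / 2.0, grid=grid, freq=sol.freq, condition=condition)


def neighbor_control_map(map_lo: ActivationMap, map_hi: ActivationMap) -> ActivationMap:
    """Voxelwise mean of the two neighbouring-bin maps (control state)."""
    if map_lo.grid.n_sources != map_hi.grid.n_sources or not np.allclose(
        map_lo.grid.positions, map_hi.grid.positions
    ):
        raise InvalidGeometryError("neighbour maps live on different grids")
    return ActivationMap(
        values=0.5 * (map_lo.values + map_hi.values),
        grid=map_lo.grid,
        freq=0.5 * (map_lo.freq + map_hi.freq),
        condition=map_lo.condition,
    )


def smooth_and_log(
    amap: ActivationMap, fwhm: float = 5.0, log: bool = True
) -> ActivationMap:
    """Gaussian smoothing on the native grid, then natural log.

    sigma = fwhm / 2.3548; the discrete kernel is normalized per source
    voxel (each voxel spreads unit mass), so total map mass is conserved
    exactly and a uniform map is unchanged up to boundary normalization.
    fwhm = 0 skips smoothing.  Before the log, values are floored at
    1e-12 times the map maximum so zeros map to a finite value; an
    all-zero map triggers a warning.
    """
    if amap.log_transformed:
        raise ConfigError("map is already log-transformed")
    v = amap.values
    if fwhm > 0:
        sigma = fwhm / 2.3548200450309493  # fwhm -> sd of the Gaussian
        pos = amap.grid.positions
        d2 = np.sum((pos[:, None, :] - pos[None, :, :]) ** 2, axis=-1)
        kernel = np.exp(-d2 / (2 * sigma**2))
        kernel /= kernel.sum(axis=0, keepdims=True)  # columns sum to 1
        v = kernel @ v
    if not log:
        return ActivationMap(
            values=v, grid=amap.grid, freq=amap.freq, condition=amap.condition
        )
    vmax = v.max(initial=0.0)
    if vmax <= 0:
        warnings.warn("all-zero activation map: every value log-floored", stacklevel=2)
        floor = np.finfo(float).tiny
    else:
        floor = 1e-12 * vmax
    return ActivationMap(
        values=np.log(np.maximum(v, floor)),
        grid=amap.grid,
        freq=amap.freq,
        condition=amap.condition,
        log_transformed=True,
    )


def _connected_components(mask: np.ndarray, neighbours: list[np.ndarray]) -> list[np.ndarray]:
    """Connected components of the supra-threshold voxel set."""
    comp = -np.ones(mask.shape[0], dtype=int)
    comps: list[list[int]] = []
    for seed in np.flatnonzero(mask):
        if comp[seed] >= 0:
            continue
        cid = len(comps)
        stack = [seed]
        comp[seed] = cid
        members = [seed]
        while stack:
            v = stack.pop()
            for nb in neighbours[v]:
                if mask[nb] and comp[nb] < 0:
                    comp[nb] = cid
                    stack.append(nb)
                    members.append(nb)
        comps.append(members)
    return [np.array(sorted(c)) for c in comps]


def voxelwise_cluster_test(
    target_maps: np.ndarray,
    control_maps: np.ndarray,
    grid: SourceGrid,
    voxel_alpha: float = 0.001,
    cluster_alpha: float = 0.01,
    n_permutations: int = 1024,
    seed: int = 0,
) -> ClusterResult:
    """One-tailed paired t (target > control) with cluster-level FWE.

    Clusters are formed from voxels exceeding the ``voxel_alpha``
    t threshold under 26-neighbourhood grid adjacency; cluster-level
    family-wise error is controlled by sign-flip permutation of the
    paired differences with a max-cluster-mass null (exhaustive
    enumeration when 2^subjects <= n_permutations).
    """
    target = np.atleast_2d(np.asarray(target_maps, dtype=float))
    control = np.atleast_2d(np.asarray(control_maps, dtype=float))
    if target.shape != control.shape:
        raise ConfigError("target and control map stacks disagree")
    s = target.shape[0]
    if s < 3:
        raise ConfigError("need at least 3 subjects")
    diffs = target - control  # (subjects, voxels)
    df = s - 1
    t_thr = float(sps.t.ppf(1 - voxel_alpha, df))

    def t_map(signs: np.ndarray) -> np.ndarray:
        # signs: (P, s); returns (P, voxels)
        means = signs @ diffs / s
        meansq = np.mean(diffs**2, axis=0)  # sign-flip invariant
        var = (meansq - means**2) * s / (s - 1)
        var = np.maximum(var, np.finfo(float).tiny)
        return means / np.sqrt(var / s)

    t_obs = t_map(np.ones((1, s)))[0]
    neighbours = grid.adjacency()
    comps = _connected_components(t_obs > t_thr, neighbours)
    if not comps:
        return ClusterResult(voxel_t=t_obs, df=df, t_threshold=t_thr, clusters=[])

    if 2**s <= n_permutations:
        signs = np.array(
            [[1 if (k >> i) & 1 else -1 for i in range(s)] for k in range(2**s)],
            dtype=float,
        )
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1.0, 1.0], size=(n_permutations, s))
    t_perm = t_map(signs)
    null_mass = np.zeros(t_perm.shape[0])
    for p_i in range(t_perm.shape[0]):
        tm = t_perm[p_i]
        cc = _connected_components(tm > t_thr, neighbours)
        if cc:
            null_mass[p_i] = max(float(tm[c].sum()) for c in cc)

    clusters = []
    n_null = len(null_mass)
    for c in comps:
        mass = float(t_obs[c].sum())
        p = float((1 + np.sum(null_mass >= mass)) / (1 + n_null))
        peak = int(c[np.argmax(t_obs[c])])
        clusters.append(
            {
                "voxels": c,
                "peak": peak,
                "peak_t": float(t_obs[peak]),
                "mass": mass,
                "p": p,
                "significant": p < cluster_alpha,
            }
        )
    clusters.sort(key=lambda d: d["p"])
    return ClusterResult(voxel_t=t_obs, df=df, t_threshold=t_thr, clusters=clusters)


def roi_extract(amap: ActivationMap, peak: int, half_size: float = 2.5) -> float:
    """Mean activation inside the cube centred at the peak voxel.

    ``half_size`` is half the cube edge in mm (default: 5 mm cube).  A
    cube smaller than the grid spacing returns the peak voxel's value.
    """
    if not 0 <= peak < amap.grid.n_sources:
        raise ConfigError("peak voxel outside the grid")
    pos = amap.grid.positions
    inside = np.all(np.abs(pos - pos[peak]) <= half_size + 1e-9, axis=1)
    if not inside.any():
        raise ConfigError("empty ROI cube")
    return float(amap.values[inside].mean())
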