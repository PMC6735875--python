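"""Electroanatomic map construction on the endocardial mesh.

Electrogram (EGM) samples are point measurements — bipolar peak-to-peak
voltage (mV) and local activation time (LAT, ms) at a catheter-tip
position. They become per-vertex maps in three steps: each sample is
assigned to its nearest mesh vertex (multiple samples average), the sampled
vertices act as fixed Dirichlet boundary values, and the remaining vertices
are filled in by relaxation — each unknown vertex solves to the mean of its
graph neighbours, i.e. the discrete Laplace equation on the vertex-edge
graph. This reproduces the linear colour interpolation a clinical mapping
platform performs between its measured points.

Voltage maps binarize at a threshold (conventionally 1.5 mV; abnormal is
strictly below). Pace sites with a stimulus-to-QRS (S-QRS) delay strictly
above 40 ms mark slow conduction; delays of 80 ms or more are flagged very
slow. Sites that fail to capture are reported separately and excluded from
the captured-site proportions.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import diags
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import spsolve
from scipy.spatial import cKDTree

from .mesh import MeshError, NodeBinaryMap, NodeScalarMap, SurfaceMesh


class EamError(ValueError):
    pass


@dataclass
class EgmSample:
    """One electrogram sampling point in the mapping frame."""

    position: np.ndarray            # (3,) mm
    bipolar_mV: float               # peak-to-peak amplitude, > 0
    lat_ms: float | None = None     # local activation time, optional
    true_class: int | None = None   # phantom ground truth (0 normal, 1 scar)

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        if not (self.bipolar_mV > 0):
            raise EamError(f"bipolar voltage must be > 0 mV, got {self.bipolar_mV}")
        if self.lat_ms is not None and not np.isfinite(self.lat_ms):
            raise EamError("LAT must be finite when present")


@dataclass
class PaceSite:
    """One pacing site; S-QRS delay is defined iff the site captured."""

    position: np.ndarray
    captured: bool
    s_qrs_ms: float | None = None
    true_class: int | None = None

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        if self.captured != (self.s_qrs_ms is not None):
            raise EamError("s_qrs_ms must be present exactly when the site captured")
        if self.s_qrs_ms is not None and self.s_qrs_ms < 0:
            raise EamError(f"S-QRS delay must be >= 0 ms, got {self.s_qrs_ms}")


def assign_egm_to_nodes(samples: list[EgmSample],
                        mesh: SurfaceMesh) -> tuple[NodeScalarMap, NodeScalarMap]:
    """Assign samples to nearest vertices; returns (voltage, LAT) maps.

    A vertex receiving several samples takes their mean; vertices with at
    least one sample are flagged known. LAT averages over samples that
    carry one.
    """
    if not samples:
        raise EamError("no EGM samples: downstream interpolation has no boundary values")
    n = mesh.n_vertices
    tree = cKDTree(mesh.vertices)
    pos = np.array([s.position for s in samples])
    _, idx = tree.query(pos)
    v_sum = np.zeros(n)
    v_cnt = np.zeros(n)
    l_sum = np.zeros(n)
    l_cnt = np.zeros(n)
    for s, i in zip(samples, idx):
        v_sum[i] += s.bipolar_mV
        v_cnt[i] += 1
        if s.lat_ms is not None:
            l_sum[i] += s.lat_ms
            l_cnt[i] += 1
    v_vals = np.full(n, np.nan)
    v_vals[v_cnt > 0] = v_sum[v_cnt > 0] / v_cnt[v_cnt > 0]
    l_vals = np.full(n, np.nan)
    l_vals[l_cnt > 0] = l_sum[l_cnt > 0] / l_cnt[l_cnt > 0]
    return (NodeScalarMap(v_vals, v_cnt > 0), NodeScalarMap(l_vals, l_cnt > 0))


def relax_interpolate(partial: NodeScalarMap, mesh: SurfaceMesh,
                      method: str = "direct",
                      gs_tol: float = 1e-10, gs_max_iter: int = 100_000) -> NodeScalarMap:
    """Fill unknown vertices by relaxation with known vertices fixed.

    Unknown vertices solve the combinatorial Laplace equation on the mesh
    graph (each unknown equals the mean of its neighbours) with the known
    vertices as Dirichlet constraints. ``method="direct"`` solves the sparse
    linear system exactly; ``method="jacobi"`` iterates the mean-of-
    neighbours update, which is the literal relaxation scheme and converges
    to the same solution.
    """
    if partial.values.shape[0] != mesh.n_vertices:
        raise MeshError("map length does not match vertex count")
    known = partial.known
    if known.sum() == 0:
        raise EamError("no known vertices: interpolation is under-determined")
    n = mesh.n_vertices
    if known.all():
        return NodeScalarMap(partial.values.copy(), known.copy())

    adj = mesh.adjacency()
    # components of the unknown-only subgraph with no known neighbour are hopeless
    ncomp, comp = connected_components(adj, directed=False)
    for c in range(ncomp):
        if not known[comp == c].any():
            raise EamError(f"mesh component {c} contains no known vertex")

    values = partial.values.copy()
    unknown = ~known
    if method == "direct":
        deg = np.asarray(adj.sum(axis=1)).ravel()
        A_uu = adj[unknown][:, unknown]
        A_uk = adj[unknown][:, known]
        L_uu = diags(deg[unknown]) - A_uu
        rhs = A_uk @ values[known]
        values[unknown] = spsolve(L_uu.tocsc(), rhs)
    elif method == "jacobi":
        deg = np.asarray(adj.sum(axis=1)).ravel()
        x = values.copy()
        x[unknown] = values[known].mean()
        for _ in range(gs_max_iter):
            x_new = (adj @ x) / deg
            x_new[known] = values[known]
            delta = np.max(np.abs(x_new[unknown] - x[unknown]))
            x = x_new
            if delta < gs_tol:
                break
        values = x
    else:
        raise ValueError(f"unknown method {method!r}")
    if not np.all(np.isfinite(values)):
        raise EamError("interpolation produced non-finite values")
    return NodeScalarMap(values, known.copy())


def binarize_map(scalar_map: NodeScalarMap, threshold_mV: float) -> NodeBinaryMap:
    """Label 1 (abnormal/scar) where value is strictly below the threshold."""
    if not np.all(np.isfinite(scalar_map.values)):
        raise EamError("map contains non-finite values; interpolate first")
    return NodeBinaryMap((scalar_map.values < threshold_mV).astype(np.uint8))


@dataclass
class SqrsSummary:
    """Per-site S-QRS conduction categories and captured-site proportions."""

    categories: list[str]           # per site: no_capture | normal | slow
    very_slow: np.ndarray           # per site bool; slow sites with delay >= very_slow_ms
    n_sites: int
    n_captured: int
    n_no_capture: int
    n_normal: int
    n_slow: int
    n_very_slow: int
    prop_normal: float = field(default=np.nan)    # over captured sites
    prop_slow: float = field(default=np.nan)
    prop_very_slow: float = field(default=np.nan)


def classify_sqrs(sites: list[PaceSite], slow_ms: float = 40.0,
                  very_slow_ms: float = 80.0) -> SqrsSummary:
    """Categorize pace sites by stimulus-to-QRS delay.

    Captured sites with delay strictly above ``slow_ms`` are slow
    conduction; at or below is normal. Delays at or above ``very_slow_ms``
    are additionally flagged very slow. Non-capturing sites are counted
    apart and excluded from the proportions.
    """
    if not (0 < slow_ms < very_slow_ms):
        raise ValueError("thresholds must satisfy 0 < slow_ms < very_slow_ms")
    cats: list[str] = []
    very = np.zeros(len(sites), dtype=bool)
    for k, s in enumerate(sites):
        if not s.captured:
            cats.append("no_capture")
            continue
        if s.s_qrs_ms > slow_ms:
            cats.append("slow")
            very[k] = s.s_qrs_ms >= very_slow_ms
        else:
            cats.append("normal")
    n_cap = sum(c != "no_capture" for c in cats)
    n_norm = sum(c == "normal" for c in cats)
    n_slow = sum(c == "slow" for c in cats)
    n_very = int(very.sum())
    return SqrsSummary(
        categories=cats, very_slow=very, n_sites=len(sites),
        n_captured=n_cap, n_no_capture=len(sites) - n_cap,
        n_normal=n_norm, n_slow=n_slow, n_very_slow=n_very,
        prop_normal=n_norm / n_cap if n_cap else np.nan,
        prop_slow=n_slow / n_cap if n_cap else np.nan,
        prop_very_slow=n_very / n_cap if n_cap else np.nan,
    )


def egm_snr(amplitude_mV: float, noise_mV: float) -> float:
    """Signal-to-noise ratio of an electrogram: amplitude / baseline noise."""
    if not (noise_mV > 0):
        raise EamError(f"noise floor must be > 0 mV, got {noise_mV}")
    return float(amplitude_mV) / float(noise_mV)
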