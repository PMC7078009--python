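"""Structural dynamics analysis in normal-mode coordinates.

Geometric distortions relative to the Franck-Condon reference are
decomposed as mass-unweighted Cartesian scalar products with normalized
normal-mode displacement vectors,

    p_i = (r_geo - r_ref) . dr_NM,i        (Angstrom),

and used for hop-inducing-geometry statistics, time-resolved coherence
analysis (signed vs unsigned ensemble means), bond-length tracking and
comparison with minimum-energy crossing-point (MECP) geometries.

Out-of-plane modes of a planar molecule have an arbitrary sign; geometries
are optionally aligned to a positive phase of a reference out-of-plane mode
by flipping the sign of every out-of-plane projection (a mirroring through
the molecular plane; in-plane projections are mirror-invariant).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .vibronic import OUT_OF_PLANE

try:  # scipy Kabsch, used only for the optional rotational pre-alignment
    from scipy.spatial.transform import Rotation as _Rotation
except ImportError:  # pragma: no cover
    _Rotation = None


@dataclass
class ModeProjection:
    mode_index: int
    p: float  # Angstrom (mass-unweighted Cartesian convention)


@dataclass
class HopGeometryStats:
    """Per-mode mean/sd of projections of hop-preceding geometries."""

    transition: tuple           # (from_label, to_label)
    mode_indices: list
    mu: np.ndarray
    sigma: np.ndarray           # population (n) convention
    n_hops: int
    empty: bool = False


@dataclass
class CoherenceSeries:
    """Signed and unsigned ensemble means of mode projections over time."""

    times: np.ndarray
    mode_indices: list
    signed_mean: np.ndarray     # (ntime, nmode)
    unsigned_mean: np.ndarray
    density: np.ndarray | None = None    # (nmode, ntime, nbins)
    bin_edges: np.ndarray | None = None


@dataclass
class BondSeries:
    atom_pair: tuple
    series: list                # per-trajectory distance arrays (Angstrom)
    times: np.ndarray

    @property
    def all_values(self) -> np.ndarray:
        return np.concatenate(self.series)

    @property
    def summary(self) -> dict:
        v = self.all_values
        return {"min": float(v.min()), "max": float(v.max()),
                "mean": float(v.mean()), "sd": float(v.std())}


def kabsch_align(geometry, reference):
    """Rigid-body (rotation + translation) alignment of ``geometry`` onto
    ``reference`` by the Kabsch algorithm (centroids superimposed)."""
    g = np.asarray(geometry, dtype=float)
    r = np.asarray(reference, dtype=float)
    gc, rc = g - g.mean(axis=0), r - r.mean(axis=0)
    rot, _ = _Rotation.align_vectors(rc, gc)
    return rot.apply(gc) + r.mean(axis=0)


def project_onto_modes(geometry, reference, modes, pre_align=False):
    """Project a Cartesian distortion onto normal-mode displacement vectors.

    Returns one :class:`ModeProjection` per mode; linear in the distortion.
    ``pre_align`` applies a Kabsch rotation/translation of the geometry onto
    the reference first (off by default; recorded by the caller).
    """
    g = np.asarray(geometry, dtype=float)
    r = np.asarray(reference, dtype=float)
    if g.shape != r.shape:
        raise ValueError(f"geometry {g.shape} and reference {r.shape} differ")
    if pre_align:
        g = kabsch_align(g, r)
    dr = (g - r).ravel()
    return [ModeProjection(m.index, float(dr @ m.displacement.ravel()))
            for m in modes]


def projection_vector(geometry, reference, modes, pre_align=False) -> np.ndarray:
    return np.array([mp.p for mp in
                     project_onto_modes(geometry, reference, modes, pre_align)])


def align_out_of_plane_phase(projections, modes, reference_mode: int):
    """Mirror geometries to a positive phase of the reference mode.

    For each geometry (row) whose projection on ``reference_mode`` is
    negative, flip the sign of every out-of-plane projection; in-plane
    projections are untouched.  Idempotent.
    """
    by_index = {m.index: m for m in modes}
    ref = by_index.get(reference_mode)
    if ref is None:
        raise ValueError(f"unknown reference mode {reference_mode}")
    if ref.character != OUT_OF_PLANE:
        raise ValueError(f"reference mode {reference_mode} is not out-of-plane")
    P = np.atleast_2d(np.asarray(projections, dtype=float)).copy()
    order = [m.index for m in modes]
    ref_col = order.index(reference_mode)
    oop = np.array([m.character == OUT_OF_PLANE for m in modes])
    flip = P[:, ref_col] < 0
    P[np.ix_(flip, oop.nonzero()[0])] *= -1.0
    return P if np.asarray(projections).ndim == 2 else P[0]


def hop_geometry_stats(ensemble, transition, modes, reference,
                       reference_mode=None, pre_align=False,
                       frustrated=False) -> HopGeometryStats:
    """Statistics of the geometries immediately preceding matching hops.

    The hop-preceding geometry is the frame at the beginning of the
    classical step in which the hop fired.  Projections are phase-aligned
    on ``reference_mode`` (if given) before the per-mode mean and
    population standard deviation are taken.
    """
    from_label, to_label = transition
    model = ensemble[0].model
    rows = []
    for tr in ensemble:
        for h in tr.hops:
            if h.frustrated != frustrated:
                continue
            if (h.from_state.split("(")[0] == from_label
                    and h.to_state.split("(")[0] == to_label):
                geo = model.cartesian_geometry(h.geometry)
                rows.append(projection_vector(geo, reference, modes, pre_align))
    if not rows:
        return HopGeometryStats(transition=tuple(transition),
                                mode_indices=[m.index for m in modes],
                                mu=np.full(len(modes), np.nan),
                                sigma=np.full(len(modes), np.nan),
                                n_hops=0, empty=True)
    P = np.asarray(rows)
    if reference_mode is not None:
        P = align_out_of_plane_phase(P, modes, reference_mode)
    return HopGeometryStats(
        transition=tuple(transition), mode_indices=[m.index for m in modes],
        mu=P.mean(axis=0), sigma=P.std(axis=0), n_hops=len(rows))


def coherence_series(ensemble, modes, reference, grid, reference_mode=None,
                     pre_align=False, n_bins=41, bin_range=None) -> CoherenceSeries:
    """Time-resolved coherence analysis of mode projections.

    For every trajectory and grid time, the frame geometry is projected on
    the modes; the ensemble mean of the signed projections and of their
    absolute values are returned together with a binned trajectory density.
    A coherent ensemble keeps |signed| close to unsigned; dephasing shows
    as the signed mean collapsing while the unsigned mean persists.
    """
    if not ensemble:
        raise ValueError("ensemble must be non-empty")
    grid = np.asarray(grid, dtype=float)
    model = ensemble[0].model
    nm = len(modes)
    all_p = np.empty((len(ensemble), len(grid), nm))
    for i, tr in enumerate(ensemble):
        rows = np.clip(np.searchsorted(tr.times, grid, side="right") - 1,
                       0, len(tr) - 1)
        for j, fr in enumerate(rows):
            geo = model.cartesian_geometry(tr.q[fr])
            all_p[i, j] = projection_vector(geo, reference, modes, pre_align)
    if reference_mode is not None:
        for j in range(len(grid)):
            all_p[:, j, :] = align_out_of_plane_phase(all_p[:, j, :], modes,
                                                      reference_mode)
    signed = all_p.mean(axis=0)
    unsigned = np.abs(all_p).mean(axis=0)
    if bin_range is None:
        lim = float(np.abs(all_p).max()) or 1.0
        bin_range = (-lim, lim)
    edges = np.linspace(bin_range[0], bin_range[1], n_bins + 1)
    density = np.empty((nm, len(grid), n_bins))
    for k in range(nm):
        for j in range(len(grid)):
            density[k, j], _ = np.histogram(all_p[:, j, k], bins=edges)
    return CoherenceSeries(times=grid, mode_indices=[m.index for m in modes],
                           signed_mean=signed, unsigned_mean=unsigned,
                           density=density, bin_edges=edges)


def _atom_index(label: str, symbols) -> int:
    """Resolve labels like 'N1', 'S7', 'H8' (symbol + 1-based position)."""
    sym = "".join(ch for ch in label if ch.isalpha())
    num = "".join(ch for ch in label if ch.isdigit())
    if not num:
        matches = [i for i, s in enumerate(symbols) if s == sym]
        if len(matches) != 1:
            raise ValueError(f"ambiguous or unknown atom label {label!r}")
        return matches[0]
    i = int(num) - 1
    if i < 0 or i >= len(symbols) or symbols[i] != sym:
        raise ValueError(f"unknown atom label {label!r}")
    return i


def bond_length_series(ensemble, atom_pair, reference=None, modes=None,
                       symbols=None, grid=None) -> BondSeries:
    """Per-frame distance of a named atom pair across the ensemble.

    Geometries are reconstructed from the model's reference geometry and
    mode displacement vectors.  Labels are element symbol + 1-based atom
    position (e.g. ``N1``, ``H8``).
    """
    model = ensemble[0].model
    symbols = symbols or model.atom_symbols
    if symbols is None:
        raise ValueError("atom symbols unavailable")
    ia, ib = (_atom_index(lb, symbols) for lb in atom_pair)
    series = []
    times = None
    for tr in ensemble:
        if grid is None:
            rows = np.arange(len(tr))
            times = tr.times
        else:
            rows = np.clip(np.searchsorted(tr.times, grid, side="right") - 1,
                           0, len(tr) - 1)
            times = np.asarray(grid, dtype=float)
        d = np.empty(len(rows))
        for j, fr in enumerate(rows):
            geo = model.cartesian_geometry(tr.q[fr])
            d[j] = np.linalg.norm(geo[ia] - geo[ib])
        series.append(d)
    return BondSeries(atom_pair=tuple(atom_pair), series=series, times=times)


def compare_to_mecp(stats: HopGeometryStats, mecp_geometry, reference, modes,
                    reference_mode=None, pre_align=False,
                    sigma_band=2.0) -> pd.DataFrame:
    """Compare hop-geometry statistics with an MECP reference geometry.

    The MECP geometry is projected onto the modes and phase-aligned like the
    hop statistics.  In-plane modes are compared as |mu - p_mecp|;
    out-of-plane modes, whose sign is arbitrary for a planar molecule, are
    flagged consistent when |p_mecp| <= |mu| + ``sigma_band``*sigma.
    """
    p = projection_vector(mecp_geometry, reference, modes, pre_align)
    if reference_mode is not None:
        p = align_out_of_plane_phase(p, modes, reference_mode)
    rows = []
    for k, m in enumerate(modes):
        oop = m.character == OUT_OF_PLANE
        if oop:
            consistent = bool(abs(p[k]) <= abs(stats.mu[k])
                              + sigma_band * stats.sigma[k])
            diff = np.nan
        else:
            diff = float(abs(stats.mu[k] - p[k]))
            consistent = np.nan
        rows.append({"mode": m.index, "character": m.character,
                     "mu_hop": stats.mu[k], "sigma_hop": stats.sigma[k],
                     "p_mecp": p[k], "abs_diff": diff,
                     "within_band": consistent})
    return pd.DataFrame(rows).set_index("mode")
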