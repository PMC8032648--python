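"""Precomputed friction tables: Γ(q) on coordinate grids plus interpolation.

The expensive resistance solves are done once, on a grid of reference
configurations (``n * prod(m_i)`` solves for ``n`` coordinates with ``m_i``
grid points each); dynamics then only interpolates.  Periodic coordinates use
truncated Fourier (trigonometric) interpolation, which reproduces grid nodes
exactly and is spectrally accurate for smooth Γ(q); 1-D non-periodic grids
may use cubic splines or a global polynomial.
"""

from __future__ import annotations

import datetime
import hashlib
import itertools
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .coordinates import FrictionMatrix, ShapeModel, friction_matrix
from .errors import ConfigError, DomainError, NumericalError, ShapeError
from .kernels import KernelConfig

__all__ = ["FrictionTable", "build_table", "trig_interp_coeffs", "trig_interp_eval"]

INTERPOLATIONS = ("fourier", "cubic_spline", "polynomial")


# --------------------------------------------------------------------------
# trigonometric interpolation helpers (uniform grids on [0, 2 pi))
# --------------------------------------------------------------------------


def trig_interp_coeffs(values: np.ndarray, n_axes: int) -> np.ndarray:
    """FFT coefficients of ``values`` over its first ``n_axes`` axes."""
    m = values.shape[:n_axes]
    return np.fft.fftn(values, axes=tuple(range(n_axes))) / np.prod(m)


def trig_interp_eval(coeffs: np.ndarray, n_axes: int, q: Sequence[float]) -> np.ndarray:
    """Evaluate the trigonometric interpolant at phases ``q`` (radians).

    Exact at grid nodes and for band-limited data (all harmonics below the
    Nyquist mode); real part taken at the end (the imaginary part is the
    odd Nyquist remainder, zero at nodes).
    """
    out = coeffs
    for ax in range(n_axes):
        m = out.shape[0]
        k = np.fft.fftfreq(m, d=1.0 / m)  # integer frequencies, Nyquist = -m/2
        phase = np.exp(1j * k * q[ax])
        out = np.tensordot(phase, out, axes=(0, 0))
    return np.real(out)


# --------------------------------------------------------------------------


@dataclass
class FrictionTable:
    """Γ sampled on a coordinate grid plus an interpolation rule.

    ``grids[i]`` holds the sorted sample values of coordinate i (for periodic
    coordinates: ``m`` uniform points on [0, 2 pi), endpoint excluded);
    ``values`` has shape ``(*m, n, n)``.
    """

    grids: tuple
    values: np.ndarray
    periodic: tuple
    interpolation: str = "fourier"
    units: tuple = ()
    coord_names: tuple = ()
    provenance: dict = field(default_factory=dict)
    _coeffs: Optional[np.ndarray] = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.grids = tuple(np.asarray(g, dtype=float) for g in self.grids)
        self.values = np.asarray(self.values, dtype=float)
        self.periodic = tuple(bool(p) for p in self.periodic)
        n_axes = len(self.grids)
        if self.values.ndim != n_axes + 2:
            raise ShapeError("values must have shape (*grid_shape, n, n)")
        for ax, g in enumerate(self.grids):
            if self.values.shape[ax] != len(g):
                raise ShapeError("grid/values shape mismatch")
            if np.any(np.diff(g) <= 0):
                raise ShapeError("grid nodes must be strictly increasing")
        if self.interpolation not in INTERPOLATIONS:
            raise ConfigError(f"unknown interpolation {self.interpolation!r}")
        if self.interpolation == "fourier" and not all(self.periodic):
            raise ConfigError("fourier interpolation requires periodic coordinates")
        if self.interpolation in ("cubic_spline", "polynomial") and self.n_coords > 1:
            raise ConfigError(f"{self.interpolation} interpolation is 1-D only")

    @property
    def n_coords(self) -> int:
        return len(self.grids)

    @property
    def n(self) -> int:
        return self.values.shape[-1]

    # ------------------------------------------------------------ queries

    def _wrap(self, q: np.ndarray) -> np.ndarray:
        q = np.array(q, dtype=float).ravel()
        if q.shape != (self.n_coords,):
            raise ShapeError(f"query must have {self.n_coords} coordinates")
        for i, per in enumerate(self.periodic):
            if per:
                q[i] = np.mod(q[i], 2.0 * np.pi)
            else:
                g = self.grids[i]
                if q[i] < g[0] - 1e-12 or q[i] > g[-1] + 1e-12:
                    raise DomainError(
                        f"coordinate {i} = {q[i]} outside table domain "
                        f"[{g[0]}, {g[-1]}] (non-periodic)"
                    )
        return q

    def interpolate(self, q) -> FrictionMatrix:
        """Entrywise interpolation of Γ at coordinates ``q``."""
        q = self._wrap(q)
        if self.interpolation == "fourier":
            if self._coeffs is None:
                sym = 0.5 * (self.values + np.swapaxes(self.values, -1, -2))
                self._coeffs = trig_interp_coeffs(sym, self.n_coords)
            m = trig_interp_eval(self._coeffs, self.n_coords, q)
        elif self.interpolation == "cubic_spline":
            m = self._spline()(q[0])
        else:  # polynomial
            m = self._poly()(q[0])
        m = 0.5 * (m + m.T)
        return FrictionMatrix(matrix=m, units=self.units, coord_names=self.coord_names)

    def _spline(self):
        if getattr(self, "_spline_fn", None) is None:
            from scipy.interpolate import CubicSpline

            g, v = self.grids[0], self.values
            if self.periodic[0]:
                g = np.append(g, g[0] + 2.0 * np.pi)
                v = np.concatenate([v, v[:1]], axis=0)
                self._spline_fn = CubicSpline(g, v, axis=0, bc_type="periodic")
            else:
                self._spline_fn = CubicSpline(g, v, axis=0)
        return self._spline_fn

    def _poly(self):
        if getattr(self, "_poly_fn", None) is None:
            from scipy.interpolate import BarycentricInterpolator

            self._poly_fn = BarycentricInterpolator(
                self.grids[0], self.values, axis=0
            )
        return self._poly_fn

    def entry_function(self, i: int, j: int):
        """Scalar function q -> Γ_ij(q) using the table's interpolation."""

        def f(*q):
            return self.interpolate(np.array(q, dtype=float)).matrix[i, j]

        return f

    # ------------------------------------------------------------ I/O

    def payload_hash(self) -> str:
        h = hashlib.sha256()
        for g in self.grids:
            h.update(np.ascontiguousarray(g).tobytes())
        h.update(np.ascontiguousarray(self.values).tobytes())
        return h.hexdigest()

    def _meta(self) -> dict:
        return {
            "periodic": list(self.periodic),
            "interpolation": self.interpolation,
            "units": list(self.units),
            "coord_names": list(self.coord_names),
            "provenance": self.provenance,
            "payload_hash": self.payload_hash(),
        }

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            grp = f.create_group("friction_table")
            for i, g in enumerate(self.grids):
                grp.create_dataset(f"grid{i}", data=g)
            grp.create_dataset("values", data=self.values)
            grp.attrs["meta"] = json.dumps(self._meta())

    @classmethod
    def from_hdf5(cls, path) -> "FrictionTable":
        import h5py

        with h5py.File(path, "r") as f:
            grp = f["friction_table"]
            meta = json.loads(grp.attrs["meta"])
            grids = []
            i = 0
            while f"grid{i}" in grp:
                grids.append(grp[f"grid{i}"][...])
                i += 1
            values = grp["values"][...]
        return cls._restore(grids, values, meta)

    def to_json(self, path) -> None:
        payload = {
            "grids": [g.tolist() for g in self.grids],
            "values": self.values.tolist(),
            "meta": self._meta(),
        }
        with open(path, "w") as f:
            json.dump(payload, f)

    @classmethod
    def from_json(cls, path) -> "FrictionTable":
        with open(path) as f:
            payload = json.load(f)
        return cls._restore(payload["grids"], payload["values"], payload["meta"])

    @classmethod
    def _restore(cls, grids, values, meta) -> "FrictionTable":
        table = cls(
            grids=tuple(np.asarray(g) for g in grids),
            values=np.asarray(values),
            periodic=tuple(meta["periodic"]),
            interpolation=meta["interpolation"],
            units=tuple(meta["units"]),
            coord_names=tuple(meta["coord_names"]),
            provenance=meta["provenance"],
        )
        stored = meta.get("payload_hash")
        if stored is not None and stored != table.payload_hash():
            raise NumericalError("friction table payload hash mismatch on load")
        return table


# --------------------------------------------------------------------------


def _grids_for(model: ShapeModel, grid_spec) -> tuple:
    """Resolve a grid specification against a model's coordinate metadata.

    ``grid_spec`` may be a single int m (uniform [0, 2 pi) grids for all
    periodic coordinates), or a sequence mixing ints (periodic coordinates)
    and explicit arrays (non-periodic coordinates).
    """
    if np.isscalar(grid_spec):
        grid_spec = [int(grid_spec)] * model.n_coords
    grids = []
    for spec, coord in zip(grid_spec, model.coords, strict=True):
        if np.isscalar(spec):
            if not coord.periodic:
                raise ConfigError(
                    "integer grid size is only valid for periodic coordinates; "
                    "pass explicit nodes"
                )
            m = int(spec)
            if m < 2:
                raise ConfigError("need at least 2 grid points per coordinate")
            grids.append(np.arange(m) * 2.0 * np.pi / m)
        else:
            grids.append(np.asarray(spec, dtype=float))
    return tuple(grids)


def build_table(
    model: ShapeModel,
    grid_spec,
    config: KernelConfig,
    interpolation: str = "fourier",
    fd_step=None,
    max_solves: int = 50_000,
) -> FrictionTable:
    """Compute Γ at every grid node (n resistance solves per node).

    Deterministic for a fixed model and config; the total solve count
    ``n * prod(m_i)`` is recorded in the table provenance.
    """
    grids = _grids_for(model, grid_spec)
    shape = tuple(len(g) for g in grids)
    n = model.n_coords
    cost = n * int(np.prod(shape))
    if cost > max_solves:
        raise ConfigError(
            f"table build needs {cost} resistance solves "
            f"(> budget {max_solves}); reduce the grid"
        )
    values = np.empty(shape + (n, n))
    for idx in itertools.product(*(range(s) for s in shape)):
        q = np.array([grids[ax][i] for ax, i in enumerate(idx)])
        try:
            values[idx] = friction_matrix(model, q, config, fd_step=fd_step).matrix
        except Exception as exc:
            raise NumericalError(
                f"friction solve failed at grid node {idx} (q = {q})"
            ) from exc
    cfg_hash = hashlib.sha256(repr(config).encode()).hexdigest()[:16]
    table = FrictionTable(
        grids=grids,
        values=values,
        periodic=tuple(c.periodic for c in model.coords),
        interpolation=interpolation,
        units=tuple(c.unit for c in model.coords),
        coord_names=tuple(f"q{i+1}" for i in range(n)),
        provenance={
            "model": model.name,
            "kernel_config_hash": cfg_hash,
            "built": datetime.datetime.now(datetime.timezone.utc).isoformat(),
            "n_solves": cost,
        },
    )
    return table
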