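"""Time reconstruction and report quantities: norms, harmonic ratios, errors.

The reported quantities mirror the standard diagnostics of harmonic imaging
studies: per-harmonic L²(Ω) norms, relative harmonic content r_m = ‖p_m‖/‖p_1‖
and the L∞(0,T; L²(Ω)) norm of the reconstructed real pressure field.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .cascade import HarmonicField
from .fem import FemOperators

__all__ = [
    "TimeField",
    "HarmonicReport",
    "reconstruct_time",
    "linf_l2_norm",
    "harmonic_ratios",
    "relative_difference",
    "pointwise_difference_map",
    "default_times",
]

#: Default number of uniform samples per period used for L∞-in-time norms.
DEFAULT_TIME_SAMPLES = 256


@dataclass
class TimeField:
    """Real nodal samples of the reconstructed field over one period."""

    times: np.ndarray
    values: np.ndarray  # (n_times, n_nodes)


def default_times(omega: float, n_samples: int = DEFAULT_TIME_SAMPLES) -> np.ndarray:
    T = 2.0 * np.pi / omega
    return np.linspace(0.0, T, n_samples, endpoint=False)


def reconstruct_time(field: HarmonicField, times: np.ndarray) -> TimeField:
    """Evaluate Re{Σ_m exp(i m ω t) p_m(x)} at the given sample instants.

    Exact trigonometric evaluation; requires alias-free sampling with at least
    2 N + 1 instants for truncation level N.
    """
    times = np.asarray(times, dtype=float)
    if times.size < 2 * field.N + 1:
        raise ValueError(
            f"need at least {2 * field.N + 1} time samples for N = {field.N}, "
            f"got {times.size}"
        )
    phases = np.exp(1j * field.omega * np.outer(times, np.arange(field.N + 1)))  # (t, m)
    stack = np.stack(field.p, axis=0)  # (m, nodes)
    values = np.real(phases @ stack)
    return TimeField(times=times, values=values)


def linf_l2_norm(tf: TimeField, ops: FemOperators) -> float:
    """max over sampled instants of the mass-matrix weighted L²(Ω) norm."""
    norms = np.sqrt(np.einsum("tn,tn->t", tf.values, (ops.M @ tf.values.T).T))
    return float(np.max(norms))


@dataclass
class HarmonicReport:
    """Per-harmonic norms and ratios of one cascade solution."""

    l2_norms_p: list[float]  # index m = 0..N
    l2_norms_v: list[float]
    ratios: dict[int, float]  # m -> ‖p_m‖ / ‖p_1‖, m >= 1
    qoi: float  # ‖Re p‖_{L∞(0,T;L²(Ω))}
    metadata: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = asdict(self)
        payload["ratios"] = {str(k): v for k, v in self.ratios.items()}
        path.write_text(json.dumps(payload, indent=2))
        return path

    @staticmethod
    def from_json(path: str | Path) -> "HarmonicReport":
        data = json.loads(Path(path).read_text())
        data["ratios"] = {int(k): v for k, v in data["ratios"].items()}
        return HarmonicReport(**data)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("m,l2_norm_p,l2_norm_v,ratio\n")
            for m, (np_, nv) in enumerate(zip(self.l2_norms_p, self.l2_norms_v)):
                r = self.ratios.get(m, "")
                fh.write(f"{m},{np_!r},{nv!r},{r!r}\n" if r != "" else f"{m},{np_!r},{nv!r},\n")
        return path


def harmonic_ratios(
    field: HarmonicField,
    ops: FemOperators,
    metadata: dict | None = None,
    n_time_samples: int = DEFAULT_TIME_SAMPLES,
) -> HarmonicReport:
    """L²(Ω) norms per harmonic, ratios r_m = ‖p_m‖/‖p_1‖ and the time-domain QoI."""
    norms_p = [ops.l2_norm(pm) for pm in field.p]
    norms_v = [ops.l2_norm(vm) for vm in field.v]
    if norms_p[1] == 0.0:
        raise ValueError("fundamental harmonic has vanishing norm; ratios undefined")
    ratios = {m: norms_p[m] / norms_p[1] for m in range(1, field.N + 1)}
    tf = reconstruct_time(field, default_times(field.omega, n_time_samples))
    qoi = linf_l2_norm(tf, ops)
    return HarmonicReport(
        l2_norms_p=norms_p,
        l2_norms_v=norms_v,
        ratios=ratios,
        qoi=qoi,
        metadata=metadata or {},
    )


def relative_difference(x, ref):
    """Relative difference |x − ref| / |ref| of scalars or report norms.

    For two :class:`HarmonicReport` objects, returns a dict with the relative
    difference of the QoI and per-harmonic relative differences of the pressure
    norms (up to the shorter truncation level).
    """
    if isinstance(x, HarmonicReport) and isinstance(ref, HarmonicReport):
        if ref.qoi == 0:
            raise ValueError("reference quantity of interest is zero")
        out = {"qoi": abs(x.qoi - ref.qoi) / ref.qoi, "per_harmonic": {}}
        n = min(len(x.l2_norms_p), len(ref.l2_norms_p))
        for m in range(1, n):
            if ref.l2_norms_p[m] == 0:
                continue
            out["per_harmonic"][m] = (
                abs(x.l2_norms_p[m] - ref.l2_norms_p[m]) / ref.l2_norms_p[m]
            )
        return out
    if ref == 0:
        raise ValueError("reference norm is zero")
    return abs(x - ref) / abs(ref)


def pointwise_difference_map(
    field_a: HarmonicField, field_b: HarmonicField, t0: float = 0.0
) -> np.ndarray:
    """Nodal |p_A(x, t0) − p_B(x, t0)| of the reconstructed real fields."""
    if field_a.n_nodes != field_b.n_nodes:
        raise ValueError("fields live on different meshes (node counts differ)")
    ms_a = np.arange(field_a.N + 1)
    ms_b = np.arange(field_b.N + 1)
    val_a = np.real(np.exp(1j * field_a.omega * t0 * ms_a) @ np.stack(field_a.p))
    val_b = np.real(np.exp(1j * field_b.omega * t0 * ms_b) @ np.stack(field_b.p))
    return np.abs(val_a - val_b)
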