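"""Synthetic dynamic lung phantom with analytic ground truth.

The phantom is the package's test substrate: a lung-shaped closed solid with
a convex costal shell (ellipsoid), a concave medial indentation (a vertical
cylindrical pocket emulating the cardiac/mediastinal groove) and a raised,
flat-topped diaphragm dome, undergoing an expiration-like maneuver from full
inspiration (frame 1) to full expiration (frame T, the reference).

Everything downstream can be validated against it because the deformation is
an explicit, analytically invertible map: per frame the solid is rasterized
exactly, surface points can be labeled from the generating primitives, and
volume/size/excursion/orientation curves are computed by direct quadrature
of the analytic geometry.

Reference-frame solid (mm, lung-local coordinates, supine axes)::

    S = { (x/ax)^2 + (y/ay)^2 + (z/az)^2 <= 1 }      (costal shell)
        ∩ { z >= z_b(x,y) }                          (diaphragm dome)
        − { (x−cx)^2 + (y−cy)^2 <= r^2, z >= z_f }   (medial pocket)

    z_b(x,y) = depth·(1 − (x/ax)^4) − ry·(y/ay)² + m_end·y

Motion (reference → frame t): posterior-anchored AP scaling
``y' = −ay + (y+ay)·k(t)``, and a vertical shear ``z' = z + δ·W(z)`` whose
amplitude δ combines dome descent (with an optional posterior–anterior
gradient) and the dome-tilt schedule; W(z) is 1 over the dome and tapers to
0 above it, so the costal shell and apex stay put.  The tilt term is written
against the *deformed* AP coordinate, which makes the sagittal-plane
orientation of every dome triangle exactly θ(t) at every frame — the
orientation truth is exact by construction, not fitted.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .imagegrid import BinaryMask, DynamicSequence

# surface labels
COSTAL, MEDIAL, DIAPHRAGMATIC, BOUNDARY = 0, 1, 2, 3
LABEL_NAMES = {COSTAL: "costal", MEDIAL: "medial",
               DIAPHRAGMATIC: "diaphragmatic", BOUNDARY: "boundary"}


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the dynamic phantom (all lengths mm, angles degrees)."""

    half_axes: tuple[float, float, float] = (58.0, 84.0, 146.0)
    dome_depth_mm: float = 32.0
    dome_y_recess_mm: float = 46.0   # parabolic AP fall-off of the dome
    indent_center: tuple[float, float] = (-40.0, 15.0)  # pocket axis (x, y)
    indent_radius_mm: float = 44.0
    indent_floor_z_mm: float = 60.0
    n_frames: int = 12
    d_max_mm: float = 20.0           # dome cranial-descent amplitude
    gradient_mm: float = 0.0         # extra descent per normalized posterior y
    ap_contraction: float = 0.0      # fractional AP expansion at inspiration
    theta_start_deg: float = 20.0    # dome tilt at full inspiration
    theta_end_deg: float = 5.0       # dome tilt at full expiration
    spacing_mm: float = 2.5
    rng_seed: int = 0
    # Control-like default: dome-dominated maneuver.  The posterior>anterior
    # excursion contrast is produced by the tilt schedule itself; AP
    # contraction is zero so CC expansion strictly exceeds AP expansion.

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.half_axes):
            raise ValueError("half axes must be positive")
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")
        if self.dome_depth_mm < 0 or self.spacing_mm <= 0:
            raise ValueError("dome depth must be >= 0 and spacing > 0")
        if self.dome_depth_mm + self.d_max_mm + abs(self.gradient_mm) > 0.8 * self.half_axes[2]:
            raise ValueError("dome deeper than lung height: self-intersecting spec")


def control_like(rng_seed: int = 0, spacing_mm: float = 2.5) -> PhantomSpec:
    """Healthy-control-like maneuver: large dome excursion, posterior>anterior
    excursion (via the tilt schedule), backwards-tilted dome at inspiration."""
    return PhantomSpec(rng_seed=rng_seed, spacing_mm=spacing_mm)


def patient_like(rng_seed: int = 0, spacing_mm: float = 2.5) -> PhantomSpec:
    """Diaphragm-weakness-like maneuver: minimal dome excursion, AP-dominated
    chest-wall contraction, near-horizontal dome whose orientation *rises*
    slightly during exhalation (the reversed tilt schedule encodes the
    anterior-dominant excursion pattern of weak diaphragms, mirroring how
    the control tilt schedule encodes posterior dominance)."""
    return PhantomSpec(d_max_mm=2.0, ap_contraction=0.15,
                       theta_start_deg=3.0, theta_end_deg=5.5,
                       rng_seed=rng_seed, spacing_mm=spacing_mm)


def diaphragm_only(rng_seed: int = 0, spacing_mm: float = 2.5) -> PhantomSpec:
    """Dome descent with the chest wall frozen (flat untilted dome)."""
    return PhantomSpec(d_max_mm=20.0, ap_contraction=0.0,
                       theta_start_deg=0.0, theta_end_deg=0.0,
                       rng_seed=rng_seed, spacing_mm=spacing_mm)


def chest_only(rng_seed: int = 0, spacing_mm: float = 2.5) -> PhantomSpec:
    """AP chest-wall contraction with the diaphragm frozen.

    The dome is perfectly flat (no tilt, no AP recession): a flat horizontal
    surface sliding horizontally sweeps exactly zero volume, so the
    diaphragm contribution of this condition is zero by construction."""
    return PhantomSpec(d_max_mm=0.0, ap_contraction=0.15, dome_y_recess_mm=0.0,
                       theta_start_deg=0.0, theta_end_deg=0.0,
                       rng_seed=rng_seed, spacing_mm=spacing_mm)


def static_spec(rng_seed: int = 0, spacing_mm: float = 2.5) -> PhantomSpec:
    """No motion at all (all frames identical)."""
    return PhantomSpec(d_max_mm=0.0, ap_contraction=0.0,
                       theta_start_deg=5.0, theta_end_deg=5.0,
                       rng_seed=rng_seed, spacing_mm=spacing_mm)


class PhantomGeometry:
    """Jittered concrete geometry + the analytic deformation of one phantom.

    The RNG seed perturbs the *shape* (axes, dome depth, pocket placement) so
    different seeds give genuinely different lungs, while the motion
    parameters (descent, tilt, contraction) stay at their nominal values so
    analytic recovery conditions are seed-invariant.
    """

    _TAPER_MM = 12.0  # height over which dome motion fades into the shell

    def __init__(self, spec: PhantomSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.rng_seed)
        ax, ay, az = spec.half_axes
        self.ax = ax * (1 + rng.uniform(-0.03, 0.03))
        self.ay = ay * (1 + rng.uniform(-0.03, 0.03))
        self.az = az * (1 + rng.uniform(-0.03, 0.03))
        self.depth = spec.dome_depth_mm * (1 + rng.uniform(-0.05, 0.05))
        self.ry = spec.dome_y_recess_mm * (1 + rng.uniform(-0.05, 0.05))
        cx, cy = spec.indent_center
        self.cx = cx + rng.uniform(-3, 3)
        self.cy = cy + rng.uniform(-3, 3)
        self.rc = spec.indent_radius_mm * (1 + rng.uniform(-0.05, 0.05))
        self.zf = spec.indent_floor_z_mm
        self.T = spec.n_frames
        # motion blending profile: full below z0, zero above z1
        tilt_bound = np.tan(np.radians(max(abs(spec.theta_start_deg),
                                           abs(spec.theta_end_deg)) + 3.0))
        ay_eff = self.ay * (1.0 + max(spec.ap_contraction, 0.0))
        if self.ry > 1e-9:
            # tilted parabola max: depth + m² ay² / (4 ry)
            dome_top = self.depth + tilt_bound ** 2 * ay_eff ** 2 / (4.0 * self.ry)
        else:
            dome_top = self.depth + tilt_bound * ay_eff
        self.z0 = dome_top + abs(spec.gradient_mm) + 3.0
        self.z1 = self.z0 + self._TAPER_MM
        if self.zf < self.z1 + 2.0:
            raise ValueError("indent floor must sit above the dome motion band")
        self._calibrate_tilt()

    # ---- schedules -------------------------------------------------------
    def tau(self, t) -> np.ndarray:
        """Normalized maneuver progress for 1-based frame index t."""
        return (np.asarray(t, float) - 1.0) / (self.T - 1)

    def s(self, t):
        return self.tau(t)

    def theta_deg(self, t):
        """Dome tilt schedule: plateau at θ_start for the first quarter of the
        maneuver, smoothstep to θ_end by 85% progress."""
        u = np.clip((self.tau(t) - 0.25) / 0.60, 0.0, 1.0)
        smooth = u * u * (3.0 - 2.0 * u)
        return self.spec.theta_start_deg + (self.spec.theta_end_deg - self.spec.theta_start_deg) * smooth

    def k(self, t):
        return 1.0 + self.spec.ap_contraction * (1.0 - self.s(t))

    # ---- tilt calibration ------------------------------------------------
    def _dome_slope_static(self, y):
        """AP slope of the static dome shape (excluding the tilt plane)."""
        return -2.0 * self.ry * np.asarray(y, float) / self.ay ** 2

    def _calibrate_tilt(self) -> None:
        """Solve for the per-frame tilt-plane coefficient m(t) such that the
        area-weighted mean sagittal-plane angle of the dome equals the
        nominal schedule θ(t) exactly.

        The dome has a static parabolic AP profile, so the pointwise angle
        atan(m + q(y)/k) averages to slightly less than atan(m); the plane
        coefficient absorbs that bias.  Solved on a coarse quadrature of the
        dome region; the region itself depends weakly on m(T), so the
        reference coefficient is iterated.
        """
        from scipy.optimize import brentq

        self.me = float(np.tan(np.radians(self.spec.theta_end_deg)))
        for _ in range(3):
            xq, yq, wq = self._dome_quadrature(step=2.0)
            q = self._dome_slope_static(yq)

            def mean_angle(m, k, grad_slope):
                ang = np.degrees(np.arctan(m + (q + grad_slope) / k))
                return float(np.average(ang, weights=wq))

            lo_m = np.tan(np.radians(self.spec.theta_end_deg - 15.0))
            hi_m = np.tan(np.radians(self.spec.theta_end_deg + 15.0))
            self.me = brentq(lambda m: mean_angle(m, 1.0, 0.0) - self.spec.theta_end_deg,
                             lo_m, hi_m, xtol=1e-12)
        self._m = np.empty(self.T)
        for t in range(1, self.T + 1):
            target = float(self.theta_deg(t))
            k = float(self.k(t))
            # slope of the gradient term: d/dy[-(1-s)·ampl(y)] = (1-s)·g/ay
            gs = (1.0 - float(self.s(t))) * self.spec.gradient_mm / self.ay
            lo_m = np.tan(np.radians(target - 15.0))
            hi_m = np.tan(np.radians(target + 15.0))
            self._m[t - 1] = brentq(
                lambda m: mean_angle(m, k, gs) - target, lo_m, hi_m, xtol=1e-12)

    def m(self, t: int) -> float:
        """Tilt-plane coefficient at 1-based frame t (calibrated)."""
        return float(self._m[int(t) - 1])

    def _dome_quadrature(self, step: float = 2.0):
        """Coarse (x, y, dA) quadrature of the analytic dome region."""
        xs = np.arange(-self.ax + step / 2, self.ax, step)
        ys = np.arange(-self.ay + step / 2, self.ay, step)
        X, Y = np.meshgrid(xs, ys, indexing="ij")
        q = (X / self.ax) ** 2 + (Y / self.ay) ** 2
        with np.errstate(invalid="ignore"):
            ztop = self.az * np.sqrt(np.clip(1.0 - q, 0.0, None))
        zb = self.z_bottom_ref(X, Y)
        dome = (q < 1.0) & (zb > -ztop) & (zb < ztop)
        xd, yd = X[dome], Y[dome]
        fx = -4.0 * self.depth * xd ** 3 / self.ax ** 4
        fy = self.me + self._dome_slope_static(yd)
        dA = np.sqrt(1.0 + fx ** 2 + fy ** 2) * step * step
        return xd, yd, dA

    # ---- reference geometry ---------------------------------------------
    def dome_profile(self, x):
        return self.depth * (1.0 - (np.asarray(x, float) / self.ax) ** 4)

    def z_bottom_ref(self, x, y):
        y = np.asarray(y, float)
        return (self.dome_profile(x) - self.ry * (y / self.ay) ** 2
                + self.me * y)

    def in_pocket_footprint(self, x, y):
        return (np.asarray(x, float) - self.cx) ** 2 + (np.asarray(y, float) - self.cy) ** 2 <= self.rc ** 2

    def ellipsoid_value(self, p):
        p = np.asarray(p, float)
        return ((p[..., 0] / self.ax) ** 2 + (p[..., 1] / self.ay) ** 2
                + (p[..., 2] / self.az) ** 2)

    def contains_reference(self, p) -> np.ndarray:
        """Membership of reference-frame points in the reference solid."""
        p = np.asarray(p, float)
        x, y, z = p[..., 0], p[..., 1], p[..., 2]
        inside = self.ellipsoid_value(p) <= 1.0
        inside &= z >= self.z_bottom_ref(x, y)
        inside &= ~(self.in_pocket_footprint(x, y) & (z >= self.zf))
        return inside

    # ---- deformation -----------------------------------------------------
    def _ampl(self, y):
        return self.spec.d_max_mm + self.spec.gradient_mm * (-np.asarray(y, float) / self.ay)

    def _delta(self, y, y_def, t):
        """Vertical shear amplitude at frame t given reference y and deformed y'."""
        return (self.m(t) * y_def - self.me * np.asarray(y, float)
                - (1.0 - self.s(t)) * self._ampl(y))

    def _W(self, z):
        z = np.asarray(z, float)
        return np.clip((self.z1 - z) / (self.z1 - self.z0), 0.0, 1.0)

    def map_points(self, points, t: int) -> np.ndarray:
        """Forward map: reference positions → positions at 1-based frame t."""
        p = np.asarray(points, float)
        x, y, z = p[..., 0], p[..., 1], p[..., 2]
        k = self.k(t)
        y_def = -self.ay + (y + self.ay) * k
        z_def = z + self._delta(y, y_def, t) * self._W(z)
        return np.stack([x, y_def, z_def], axis=-1)

    def unmap_points(self, points, t: int) -> np.ndarray:
        """Inverse map: frame-t positions → reference positions (exact)."""
        p = np.asarray(points, float)
        x, y_def, z_def = p[..., 0], p[..., 1], p[..., 2]
        k = self.k(t)
        y = -self.ay + (y_def + self.ay) / k
        d = self._delta(y, y_def, t)
        span = self.z1 - self.z0
        # piecewise-linear W: invert branch by the image of the breakpoints
        z_low = z_def - d                                   # if z <= z0
        denom = 1.0 - d / span
        z_mid = (z_def - d * self.z1 / span) / denom        # if z0 < z < z1
        z = np.where(z_def <= self.z0 + d, z_low,
                     np.where(z_def < self.z1, z_mid, z_def))
        return np.stack([x, y, z], axis=-1)

    def displacement_provider(self):
        """Callable ``(points, t) -> positions`` (t 1-based; identity at t=T)."""
        def provider(points, t: int) -> np.ndarray:
            if not 1 <= t <= self.T:
                raise ValueError(f"frame index {t} outside [1..{self.T}]")
            return self.map_points(points, t)
        return provider

    # ---- rasterization ---------------------------------------------------
    def grid_definition(self):
        h = self.spec.spacing_mm
        margin = 3 * h
        k1 = self.k(1)
        ymax = -self.ay + (self.ay + self.ay) * max(k1, 1.0)
        # lowest surface point over all frames: dome rim (profile = 0) plus the
        # most negative shear amplitude at either AP extreme of frame 1
        ys = np.array([-self.ay, self.ay])
        yd1 = -self.ay + (ys + self.ay) * k1
        base_min = -(self.ry + abs(self.me) * self.ay)
        zmin = float(min(0.0, base_min + min(self._delta(ys, yd1, 1).min(), 0.0)) - margin)
        lo = np.array([-self.ax - margin, -self.ay - margin, zmin - margin])
        hi = np.array([self.ax + margin, ymax + margin, self.az + margin])
        shape = tuple(int(np.ceil((b - a) / h)) + 1 for a, b in zip(lo, hi))
        return lo, h, shape

    def rasterize_frame(self, t: int) -> BinaryMask:
        lo, h, shape = self.grid_definition()
        axes = [lo[i] + np.arange(shape[i]) * h for i in range(3)]
        X, Y, Z = np.meshgrid(*axes, indexing="ij")
        pts = np.stack([X, Y, Z], axis=-1)
        ref = self.unmap_points(pts, t)
        inside = self.contains_reference(ref)
        return BinaryMask(inside, (h, h, h), tuple(lo))


class PhantomTruth:
    """Analytic ground truth: labels, curves and features of a phantom.

    Scalar curves and area-weighted features are evaluated by direct
    quadrature on a fine column grid of the analytic geometry (exact in z,
    second-order in the transverse step).
    """

    def __init__(self, geom: PhantomGeometry, grid_step_mm: float = 1.0):
        self.geom = geom
        self.spec = geom.spec
        self._build_columns(grid_step_mm)

    # ---- surface labeling ------------------------------------------------
    def label_points(self, points, band_mm: float = 2.0) -> np.ndarray:
        """Label surface points {costal, medial, diaphragmatic}; points within
        ``band_mm`` of a region border are marked BOUNDARY and should be
        excluded from agreement scoring."""
        g = self.geom
        p = np.asarray(points, float)
        x, y, z = p[..., 0], p[..., 1], p[..., 2]

        # approximate unsigned distances to each generating primitive
        ev = g.ellipsoid_value(p)
        grad = 2.0 * np.sqrt((x / g.ax ** 2) ** 2 + (y / g.ay ** 2) ** 2
                             + (z / g.az ** 2) ** 2)
        r_shell = np.abs(ev - 1.0) / np.maximum(grad, 1e-12)

        fx = -4.0 * g.depth * x ** 3 / g.ax ** 4
        fy = g.me + g._dome_slope_static(y)
        slope = np.sqrt(1.0 + fx ** 2 + fy ** 2)
        r_dome = np.abs(z - g.z_bottom_ref(x, y)) / slope

        rho = np.hypot(x - g.cx, y - g.cy)
        wall_ok = z >= g.zf - band_mm
        r_wall = np.where(wall_ok, np.abs(rho - g.rc), np.inf)
        shelf_ok = rho <= g.rc + band_mm
        r_shelf = np.where(shelf_ok, np.abs(z - g.zf), np.inf)
        r_pocket = np.minimum(r_wall, r_shelf)

        res = np.stack([r_shell, r_pocket, r_dome], axis=-1)
        order = np.argsort(res, axis=-1)
        labels = order[..., 0].astype(int)  # 0 costal, 1 medial, 2 diaphragmatic
        second = np.take_along_axis(res, order, axis=-1)[..., 1]
        labels = np.where(second < band_mm, BOUNDARY, labels)
        return labels

    # ---- column quadrature ----------------------------------------------
    def _build_columns(self, h: float) -> None:
        g = self.geom
        xs = np.arange(-g.ax + h / 2, g.ax, h)
        ys = np.arange(-g.ay + h / 2, g.ay, h)
        X, Y = np.meshgrid(xs, ys, indexing="ij")
        q = (X / g.ax) ** 2 + (Y / g.ay) ** 2
        valid = q < 1.0
        ztop = np.where(valid, g.az * np.sqrt(np.clip(1.0 - q, 0.0, None)), -np.inf)
        zb = g.z_bottom_ref(X, Y)
        zlo = np.maximum(zb, -ztop)
        zhi = np.where(g.in_pocket_footprint(X, Y), np.minimum(ztop, g.zf), ztop)
        nonempty = valid & (zhi > zlo)
        self._h = h
        self._X, self._Y = X[nonempty], Y[nonempty]
        self._zlo, self._zhi = zlo[nonempty], zhi[nonempty]
        self._dome = (zb[nonempty] > -ztop[nonempty] + 1e-9) & (self._zhi > zb[nonempty])
        # dome surface metric and reference area weights
        xd, yd = self._X[self._dome], self._Y[self._dome]
        fx = -4.0 * g.depth * xd ** 3 / g.ax ** 4
        fy = g.me + g._dome_slope_static(yd)
        self._dome_dA = np.sqrt(1.0 + fx ** 2 + fy ** 2) * h * h
        self._dome_zb = self._zlo[self._dome]

    def _delta_cols(self, y, t):
        g = self.geom
        y_def = -g.ay + (y + g.ay) * g.k(t)
        return g._delta(y, y_def, t)

    def volume_curve(self) -> np.ndarray:
        """V(t), mm³, t = 1..T (exact change-of-variables quadrature)."""
        g = self.geom
        out = np.empty(g.T)
        dxdy = self._h ** 2
        for t in range(1, g.T + 1):
            d = self._delta_cols(self._Y, t)
            w = g._W(self._zhi) - g._W(self._zlo)
            out[t - 1] = g.k(t) * np.sum((self._zhi - self._zlo) + d * w) * dxdy
        return out

    def cc_curve(self) -> np.ndarray:
        """CC size: lung apex z minus diaphragm (dome) apex z, per frame."""
        g = self.geom
        apex = float(self._zhi.max())
        out = np.empty(g.T)
        for t in range(1, g.T + 1):
            d = self._delta_cols(self._Y[self._dome], t)
            out[t - 1] = apex - float((self._dome_zb + d).max())
        return out

    def ap_curve(self) -> np.ndarray:
        g = self.geom
        span = float(self._Y.max() - self._Y.min())
        return np.array([g.k(t) * span for t in range(1, g.T + 1)])

    def y_mid_reference(self) -> float:
        return float((self._Y.max() + self._Y.min()) / 2.0)

    # ---- features --------------------------------------------------------
    def dome_excursions(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-column diaphragm excursion value (signed, at max magnitude over
        t, relative to frame 1), its area weights and reference y."""
        g = self.geom
        yd = self._Y[self._dome]
        disp = np.stack([self._delta_cols(yd, t) - self._delta_cols(yd, 1)
                         for t in range(1, g.T + 1)], axis=0)
        idx = np.argmax(np.abs(disp), axis=0)
        val = disp[idx, np.arange(disp.shape[1])]
        return val, self._dome_dA, yd

    def swept_curves(self) -> dict[str, np.ndarray]:
        """Per-step displaced volumes (mm³, inward/expiration positive) for the
        diaphragmatic, medial and costal surfaces."""
        g = self.geom
        dv = self.volume_curve()
        dome_d, dome_m, dome_c = [], [], []
        yd = self._Y[self._dome]
        dxdy = self._h ** 2
        fy_static = g._dome_slope_static(yd)
        for t in range(1, g.T):
            kbar = 0.5 * (g.k(t) + g.k(t + 1))
            fybar = fy_static + 0.5 * (g.m(t) + g.m(t + 1))
            ddelta = self._delta_cols(yd, t + 1) - self._delta_cols(yd, t)
            duy = (g.k(t + 1) - g.k(t)) * (yd + g.ay)
            dome_d.append(float(np.sum((ddelta - fybar * duy) * kbar) * dxdy))
            dome_m.append(self._pocket_flux(t))
            dome_c.append((dv[t - 1] - dv[t]) - dome_d[-1] - dome_m[-1])
        return {"diaphragm": np.array(dome_d), "medial": np.array(dome_m),
                "costal": np.array(dome_c)}

    def _pocket_flux(self, t: int) -> float:
        """Inward volume swept by the pocket (medial) surface in step t→t+1."""
        g = self.geom
        dk = g.k(t + 1) - g.k(t)
        if dk == 0.0:
            return 0.0
        n_phi = 256
        phi = np.linspace(0, 2 * np.pi, n_phi, endpoint=False)
        xw = g.cx + g.rc * np.cos(phi)
        yw = g.cy + g.rc * np.sin(phi)
        q = (xw / g.ax) ** 2 + (yw / g.ay) ** 2
        ztop = np.where(q < 1, g.az * np.sqrt(np.clip(1 - q, 0, None)), g.zf)
        height = np.clip(ztop - g.zf, 0.0, None)
        # outward normal of the solid points toward the pocket axis
        ny = -(yw - g.cy) / g.rc
        duy = dk * (yw + g.ay)
        darc = g.rc * (2 * np.pi / n_phi)
        return float(-np.sum(ny * duy * height) * darc)

    def features(self) -> dict[str, float]:
        g = self.geom
        V = self.volume_curve()
        CC = self.cc_curve()
        AP = self.ap_curve()
        val, w, yd = self.dome_excursions()
        a4 = float(np.sum(val * w) / np.sum(w))
        ymid = self.y_mid_reference()
        post, ant = yd < ymid, yd >= ymid
        post_mean = float(np.sum(val[post] * w[post]) / np.sum(w[post]))
        ant_mean = float(np.sum(val[ant] * w[ant]) / np.sum(w[ant]))
        theta = np.array([g.theta_deg(t) for t in range(1, g.T + 1)])
        total = abs(V[-1] - V[0])
        feats = {
            "B1": V[-1] * 1e-6, "B2": (V[0] - V[-1]) * 1e-6,
            "B3": V[0] / V[-1], "B4": CC[0] / CC[-1], "B5": AP[0] / AP[-1],
            "A4": a4, "A5": post_mean - ant_mean,
            "A4_posterior": post_mean, "A4_anterior": ant_mean,
            "A6": float(theta[0]),
        }
        feats["B6"] = feats["B4"] / feats["B5"]
        swept = self.swept_curves()
        dvd, dvc = float(swept["diaphragm"].sum()), float(swept["costal"].sum())
        feats["A1"] = dvd * 1e-6
        feats["A2"] = dvc * 1e-6
        feats["A3"] = dvd / (dvd + dvc) if (dvd + dvc) != 0 else float("nan")
        if total > 0:
            cum = np.abs(V - V[0])
            t_s = int(np.argmax(cum >= 0.1 * total))
            t_e = int(np.argmax(cum >= 0.9 * total))
            window = theta[t_s:t_e + 1] - theta[t_s]
            feats["A7"] = float(window[np.argmax(np.abs(window))])
        else:
            feats["A7"] = 0.0
        return feats


@dataclass
class PhantomResult:
    sequence: DynamicSequence
    displacement: object            # callable (points, t 1-based) -> positions
    truth: PhantomTruth
    geometry: PhantomGeometry

    @property
    def reference_mask(self) -> BinaryMask:
        return self.sequence.frames[-1]


def generate_phantom(spec: PhantomSpec, frames: Optional[list[int]] = None) -> PhantomResult:
    """Generate the dynamic phantom: per-frame binary masks, the analytic
    displacement provider, and the ground truth.

    ``frames`` optionally restricts which 1-based frames are rasterized (the
    displacement provider and truth remain defined for all T frames); the
    returned sequence then holds just those masks, in frame order.  This
    matters only for speed: partitioning needs frame T alone.
    """
    geom = PhantomGeometry(spec)
    wanted = list(range(1, spec.n_frames + 1)) if frames is None else sorted(set(frames))
    if wanted[0] < 1 or wanted[-1] > spec.n_frames:
        raise ValueError("frame indices out of range")
    if len(wanted) < 2:
        raise ValueError("rasterize at least 2 frames (use PhantomGeometry."
                         "rasterize_frame for a single mask)")
    seq = DynamicSequence([geom.rasterize_frame(t) for t in wanted])
    truth = PhantomTruth(geom)
    return PhantomResult(seq, geom.displacement_provider(), truth, geom)
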