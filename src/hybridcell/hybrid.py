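"""Bidirectional 1D/3D co-simulation driver and parameter studies.

One shared timestep advances both models with an explicit staggered (loose)
coupling, one data exchange per step:

1. the cable solver steps the membrane potential, its calcium current
   evaluated from the previous step's back-mapped per-compartment [Ca];
2. the fresh compartment potentials are mapped onto the membrane surface
   vertices (nearest-neighbor by default);
3. the Borg-Graham channel gates advance one explicit-Euler step at the
   mapped potentials and yield the GHK boundary-flux density;
4. the 3D calcium solver takes one implicit-Euler step with that Neumann
   influx;
5. the membrane-adjacent concentration field is surface-averaged per
   compartment patch and handed back to the cable model.

The module also scripts the reference parameter studies: sweeps of the
cytosolic diffusion coefficient, of the VGCC surface density, and of the
hindrance of an intracellular obstacle, each reporting peak probe
amplitudes and an OLS linear fit (slope, R^2, two-sided p of the slope).
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace

import numpy as np
import yaml
from scipy import stats

from . import cable1d, calcium3d, mapping, meshgen, morphology, vgcc
from .cable1d import MembraneParams, ObstacleSpec, StimProtocol
from .calcium3d import BufferParams
from .errors import ConfigError
from .vgcc import BGGate, BGParams

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# configuration

@dataclass
class MorphologySource:
    kind: str = "cylinder"          # cylinder | y_branch | soma_tree | swc
    path: str | None = None         # for kind == swc
    dims: dict = field(default_factory=dict)

    def build(self, seed: int = 0) -> morphology.MorphologyGraph:
        if self.kind == "swc":
            if not self.path:
                raise ConfigError("morphology kind 'swc' needs a path")
            return morphology.read_swc(self.path)
        return morphology.generate_synthetic(self.kind, seed=seed,
                                             **self.dims)


@dataclass
class HybridConfig:
    """Full experiment description (keys mirror the reference parameter
    sheet: dt, stim.dur, stim.amp, diffusion in um^2/s, density in um^-2)."""

    morphology: MorphologySource = field(default_factory=MorphologySource)
    mesh_h: float | None = None            # um; overrides n_circle
    n_circle: int = 16
    compartment_max_length: float = 1.0    # um
    dt: float = 0.1                        # ms, shared by both models
    t_total: float = 100.0                 # ms
    stim: StimProtocol = field(default_factory=StimProtocol)
    membrane: MembraneParams = field(default_factory=MembraneParams)
    ca_diffusion_um2_per_s: float = 100.0  # Table-style units
    buffers: BufferParams = field(default_factory=BufferParams)
    channel: BGParams = field(default_factory=lambda: vgcc.N_TYPE)
    ca_o_mM: float = 1.6
    ca0_uM: float = 0.1
    obstacles: list[ObstacleSpec] = field(default_factory=list)
    mapping_mode: str = "nearest"
    mapping_k: int = 4
    mapping_cutoff: float | None = None
    # optional space-dependent channel placement: list of
    # {edge, lo, hi} arc-length windows [um] that carry channels;
    # None = homogeneous over the whole membrane
    density_regions: list[dict] | None = None
    probes: np.ndarray | None = None       # (m, 3) um; default: auto
    record_fields_every: int = 0           # steps; 0 = never
    seed: int = 0

    def __post_init__(self):
        n = self.t_total / self.dt
        if abs(n - round(n)) > 1e-9:
            raise ConfigError("t_total must be an integer multiple of dt")

    @property
    def d_ca(self) -> float:
        """Calcium diffusion coefficient in internal units [um^2/ms]."""
        return self.ca_diffusion_um2_per_s * 1.0e-3

    @classmethod
    def from_yaml(cls, path) -> "HybridConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "HybridConfig":
        kw = dict(raw)
        if "morphology" in kw:
            m = dict(kw["morphology"])
            kw["morphology"] = MorphologySource(
                kind=m.pop("kind", "cylinder"), path=m.pop("path", None),
                dims=m)
        if "stim" in kw:
            s = dict(kw["stim"])
            kw["stim"] = StimProtocol(
                compartment=s.get("compartment"),
                amplitude=s.get("amp", s.get("amplitude", 0.1)),
                onset=s.get("onset", 0.0),
                duration=s.get("dur", s.get("duration", 10.0)))
        if "membrane" in kw:
            kw["membrane"] = MembraneParams(**kw["membrane"])
        if "buffers" in kw:
            kw["buffers"] = BufferParams(**kw["buffers"])
        if "channel" in kw:
            c = dict(kw["channel"])
            gates = {}
            for gname in ("gate_k", "gate_l"):
                if gname in c:
                    gates[gname] = BGGate(**c.pop(gname))
                else:
                    gates[gname] = getattr(vgcc.N_TYPE, gname)
            kw["channel"] = BGParams(**gates, **c)
        if "obstacles" in kw:
            kw["obstacles"] = [ObstacleSpec(**o) for o in kw["obstacles"]]
        if "probes" in kw and kw["probes"] is not None:
            kw["probes"] = np.asarray(kw["probes"], float)
        unknown = set(kw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kw)


def default_probes(graph: morphology.MorphologyGraph) -> np.ndarray:
    """Measuring points on the longest neurite's midpoint cross-section:
    membrane-adjacent (0.9 r), intermediate (0.45 r) and on-axis."""
    edges = morphology.edge_order(graph)
    pos, rad = graph.positions, graph.radii
    lengths = [np.linalg.norm(pos[c] - pos[p]) for p, c in edges]
    p, c = edges[int(np.argmax(lengths))]
    a, b = pos[p], pos[c]
    u = (b - a) / np.linalg.norm(b - a)
    mid = 0.5 * (a + b)
    r = 0.5 * (rad[p] + rad[c])
    # radial direction perpendicular to the axis
    trial = np.array([0.0, 0.0, 1.0])
    if abs(u @ trial) > 0.9:
        trial = np.array([0.0, 1.0, 0.0])
    v = np.cross(u, trial)
    v /= np.linalg.norm(v)
    return np.array([mid + 0.9 * r * v, mid + 0.45 * r * v, mid])


# ---------------------------------------------------------------------------
# results container

@dataclass
class HybridRun:
    """Synchronized 1D/3D time series of one hybrid simulation."""

    t: np.ndarray                   # (n+1,) ms
    V: np.ndarray                   # (n+1, n_comp) mV
    ca_comp: np.ndarray             # (n+1, n_comp) uM, back-mapped
    probes: np.ndarray              # (n+1, n_probes) uM
    probe_points: np.ndarray
    flux_1d_amol_per_ms: np.ndarray  # (n+1,) total 1D calcium influx
    flux_3d_amol_per_ms: np.ndarray  # (n+1,) total 3D boundary influx
    ca0_uM: float
    meta: dict = field(default_factory=dict)
    fields: list = field(default_factory=list)

    def peak_amplitude(self, probe: int = 0) -> float:
        """Peak [Ca] elevation above baseline at the probe [uM]."""
        return float(self.probes[:, probe].max() - self.ca0_uM)

    def save_h5(self, path) -> None:
        import h5py
        with h5py.File(path, "w") as fh:
            for name in ("t", "V", "ca_comp", "probes", "probe_points",
                         "flux_1d_amol_per_ms", "flux_3d_amol_per_ms"):
                fh.create_dataset(name, data=getattr(self, name))
            fh.attrs["ca0_uM"] = self.ca0_uM
            for k, v in self.meta.items():
                if np.isscalar(v):
                    fh.attrs[k] = v


# unit bridges for the flux comparison record
_NA_TO_AMOL_PER_MS = 1.0e6 / (2 * 96485.33212)   # nA -> amol/ms (z = 2)
_UM3_UM_TO_AMOL = 1.0e-3                          # uM*um^3/ms -> amol/ms


# ---------------------------------------------------------------------------
# driver

def run(config: HybridConfig, correct_1d_obstacles: bool = True
        ) -> HybridRun:
    """Execute one bidirectionally coupled 1D/3D simulation.

    ``correct_1d_obstacles=False`` skips the electrical diameter
    correction (needed for sealing obstacles, H = 1, where no finite
    effective diameter exists)."""
    t_setup = time.time()
    graph = config.morphology.build(config.seed)
    model = morphology.build_compartments(graph,
                                          config.compartment_max_length)
    model_1d = cable1d.apply_obstacle_correction(model, config.obstacles) \
        if (config.obstacles and correct_1d_obstacles) else model
    h = config.mesh_h
    if h is None:
        h = meshgen.resolution_from_n_circle(graph, config.n_circle)
    surface, volume = meshgen.build_mesh_pair(graph, h,
                                              config.obstacles or None)
    labels, patch_areas, cyl_areas = meshgen.assign_patches(surface, model)

    cable = cable1d.CableModel(model_1d, config.membrane,
                               channel=config.channel,
                               ca_o_mM=config.ca_o_mM)
    solver = calcium3d.CalciumSolver(volume, np.eye(3) * config.d_ca,
                                     config.buffers)

    # static mapping: membrane surface vertices <- compartment centers
    mem_verts = volume.boundary_vertices(meshgen.REGION_MEMBRANE)
    cap_verts = volume.boundary_vertices(meshgen.REGION_CAP)
    flux_verts = np.unique(np.concatenate([mem_verts, cap_verts]))
    index = mapping.build_index(model.centers)
    targets = volume.vertices[flux_verts]
    nn_idx, _ = mapping.nearest(index, targets)
    nn_idx = np.atleast_1d(nn_idx)
    w_mem = volume.boundary_vertex_areas(meshgen.REGION_MEMBRANE) \
        + volume.boundary_vertex_areas(meshgen.REGION_CAP)
    w_at_flux = w_mem[flux_verts]

    # per-vertex channel density (space-dependent placement supported)
    density_at_flux = None
    if config.density_regions is not None:
        sdf = meshgen.GeometrySDF(graph)
        edge_idx, arc = sdf.nearest_edge_arc(targets)
        density_at_flux = np.zeros(len(targets))
        for region in config.density_regions:
            sel = (edge_idx == int(region.get("edge", 0))) \
                & (arc >= float(region["lo"])) & (arc <= float(region["hi"]))
            density_at_flux[sel] = config.channel.density
        # matching per-compartment coverage for the 1D calcium current
        scale = np.zeros(n_comp_scale := len(model))
        for i, comp in enumerate(model.compartments):
            lo, hi = comp.arc_start, comp.arc_start + comp.length
            for region in config.density_regions:
                if int(region.get("edge", 0)) != comp.branch_edge:
                    continue
                overlap = min(hi, float(region["hi"])) \
                    - max(lo, float(region["lo"]))
                if overlap > 0:
                    scale[i] += overlap / comp.length
        cable.density_scale = np.clip(scale, 0.0, 1.0)

    probes_xyz = config.probes if config.probes is not None \
        else default_probes(graph)
    locator = calcium3d.probe_locator(volume, probes_xyz)

    # back-mapping as a static linear operator over boundary values
    backmap = _backmap_matrix(surface, labels, cyl_areas,
                              model.parent_indices)

    n_steps = int(round(config.t_total / config.dt))
    n_comp = len(model)
    state = cable.initial_state(config.ca0_uM)
    field3 = calcium3d.Field3D.uniform(len(volume.vertices), config.ca0_uM,
                                       config.buffers)
    chan_state = vgcc.ChannelState.at_equilibrium(
        state.V[nn_idx], config.channel)
    solver.prepare(config.dt, field3)
    cable.prime_gates(state, config.dt)

    out = HybridRun(
        t=np.arange(n_steps + 1) * config.dt,
        V=np.empty((n_steps + 1, n_comp)),
        ca_comp=np.empty((n_steps + 1, n_comp)),
        probes=np.empty((n_steps + 1, len(probes_xyz))),
        probe_points=np.asarray(probes_xyz, float),
        flux_1d_amol_per_ms=np.zeros(n_steps + 1),
        flux_3d_amol_per_ms=np.zeros(n_steps + 1),
        ca0_uM=config.ca0_uM,
        meta={"n_vertices": len(volume.vertices),
              "n_tets": len(volume.tets),
              "n_compartments": n_comp,
              "mesh_h": h,
              "d_ca_um2_per_ms": config.d_ca,
              "density_per_um2": config.channel.density},
    )
    out.V[0] = state.V
    out.ca_comp[0] = state.ca
    out.probes[0] = calcium3d.probe(field3.c, locator)

    use_simple_map = config.mapping_mode == "nearest"
    frame_targets = targets

    for step in range(1, n_steps + 1):
        # (1) cable with I_Ca from the previous back-mapped concentrations
        i_ca = cable.calcium_current(state)
        state = cable.step(state, config.stim, config.dt, i_ca_nA=i_ca)
        # (2) potential mapping 1D -> 3D
        if use_simple_map:
            v_vert = state.V[nn_idx]
        else:
            frame = mapping.PotentialFrame(state.t, state.V)
            v_vert = mapping.map_potentials(
                index, frame, frame_targets, mode=config.mapping_mode,
                k=config.mapping_k, cutoff=config.mapping_cutoff)
        # (3) channel gating + GHK boundary flux at local [Ca]
        chan_state = vgcc.gate_step_euler(chan_state, v_vert, config.dt,
                                          config.channel)
        phi = vgcc.boundary_flux(v_vert, chan_state,
                                 field3.c[flux_verts], config.ca_o_mM,
                                 config.channel, density=density_at_flux)
        f_ext = np.zeros(len(volume.vertices))
        f_ext[flux_verts] = phi * w_at_flux
        # (4) 3D reaction-diffusion step
        field3 = solver.step(field3, f_ext, config.dt)
        # (5) concentration back-mapping 3D -> 1D
        state.ca = backmap @ field3.c[surface.vertex_map]
        out.V[step] = state.V
        out.ca_comp[step] = state.ca
        out.probes[step] = calcium3d.probe(field3.c, locator)
        out.flux_3d_amol_per_ms[step] = f_ext.sum() * _UM3_UM_TO_AMOL
        out.flux_1d_amol_per_ms[step] = -i_ca.sum() * _NA_TO_AMOL_PER_MS
        if config.record_fields_every and \
                step % config.record_fields_every == 0:
            out.fields.append((state.t, field3.c.copy()))
    out.meta["wall_time_s"] = time.time() - t_setup
    logger.info("hybrid run finished: %d steps, %d vertices, %.1f s",
                n_steps, out.meta["n_vertices"], out.meta["wall_time_s"])
    return out


def _backmap_matrix(surface, labels, cyl_areas, parent_indices):
    """Sparse (n_comp x n_surface_verts) operator realizing the
    surface-average back-mapping; row i applied to boundary values gives
    the compartment-i concentration (area-weighted patch mean times the
    cylinder/patch area ratio)."""
    import scipy.sparse as sp
    n_comp = len(cyl_areas)
    areas = surface.triangle_areas()
    n_sv = len(surface.vertices)
    rows, cols, vals = [], [], []
    patch_area = np.zeros(n_comp)
    valid = labels >= 0
    np.add.at(patch_area, labels[valid], areas[valid])
    for corner in range(3):
        rows.append(labels[valid])
        cols.append(surface.triangles[valid, corner])
        vals.append(areas[valid] / 3.0)
    P = sp.coo_matrix((np.concatenate(vals),
                       (np.concatenate(rows), np.concatenate(cols))),
                      shape=(n_comp, n_sv)).tocsr()
    scale = np.zeros(n_comp)
    nz = patch_area > 0
    scale[nz] = cyl_areas[nz] / patch_area[nz] ** 2
    P = sp.diags(scale) @ P
    # empty patches inherit the nearest ancestor's row
    for i in np.nonzero(~nz)[0]:
        j = i
        hops = 0
        while patch_area[j] <= 0 and parent_indices[j] >= 0 \
                and hops < n_comp:
            j = parent_indices[j]
            hops += 1
        if patch_area[j] > 0:
            P = P.tolil()
            P[i] = P[j]
            P = P.tocsr()
            logger.warning("compartment %d has an empty membrane patch; "
                           "inheriting ancestor %d", i, j)
    return P


# ---------------------------------------------------------------------------
# parameter studies

def linear_fit(x, y) -> dict:
    """OLS fit with R^2 and the two-sided t-test p-value of the slope."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2 or np.ptp(x) == 0:
        logger.warning("degenerate sweep (no variation in x); fit rejected")
        return {"ok": False, "reason": "rank-deficient design",
                "slope": np.nan, "intercept": np.nan, "r2": np.nan,
                "p": np.nan}
    res = stats.linregress(x, y)
    return {"ok": True, "slope": res.slope, "intercept": res.intercept,
            "r2": res.rvalue ** 2, "p": res.pvalue,
            "stderr": res.stderr}


def sweep_diffusion(config: HybridConfig, d_values_um2_per_s,
                    probe: int = 0) -> dict:
    """Hybrid runs across cytosolic diffusion coefficients [um^2/s];
    returns the peak-amplitude table and the OLS fit of peak vs D."""
    peaks, runs = [], []
    for d in d_values_um2_per_s:
        cfg = replace(config, ca_diffusion_um2_per_s=float(d))
        r = run(cfg)
        peaks.append(r.peak_amplitude(probe))
        runs.append(r)
        logger.info("D = %g um^2/s -> peak %.4f uM", d, peaks[-1])
    fit = linear_fit(np.asarray(d_values_um2_per_s, float), peaks)
    return {"x": np.asarray(d_values_um2_per_s, float),
            "x_name": "ca_diffusion_um2_per_s",
            "peaks_uM": np.asarray(peaks), "fit": fit, "runs": runs}


def sweep_density(config: HybridConfig, rho_values_per_um2,
                  probe: int = 0) -> dict:
    """Hybrid runs across VGCC surface densities [um^-2]."""
    peaks, runs = [], []
    for rho in rho_values_per_um2:
        cfg = replace(config, channel=config.channel.with_density(float(rho)))
        r = run(cfg)
        peaks.append(r.peak_amplitude(probe))
        runs.append(r)
        logger.info("rho = %g um^-2 -> peak %.4f uM", rho, peaks[-1])
    fit = linear_fit(np.asarray(rho_values_per_um2, float), peaks)
    return {"x": np.asarray(rho_values_per_um2, float),
            "x_name": "vgcc_density_per_um2",
            "peaks_uM": np.asarray(peaks), "fit": fit, "runs": runs}


def sweep_obstacle(config: HybridConfig, h_values, obstacle: ObstacleSpec,
                   probe_offset_um: float = 1.0) -> dict:
    """Hybrid runs across obstacle hindrance factors.

    Probes sit on the neurite axis just proximal ('before') and distal
    ('behind') of the obstacle.  The 1D model's compartment diameters are
    corrected per run; H = 1 seals the 3D domain but the electrical
    correction is refused (d_new = 0), so the cable runs uncorrected.
    """
    graph = config.morphology.build(config.seed)
    geom = meshgen.GeometrySDF(graph)
    a, u, L, *_ = geom._edge_geom[obstacle.edge]
    s0 = obstacle.arc_position
    before_xyz = a + (s0 - obstacle.length / 2 - probe_offset_um) * u
    behind_xyz = a + (s0 + obstacle.length / 2 + probe_offset_um) * u
    probes = np.array([before_xyz, behind_xyz])
    series = []
    for hval in h_values:
        obs = replace(obstacle, hindrance=float(hval))
        obstacles = [] if hval == 0 else [obs]
        cfg = replace(config, obstacles=obstacles, probes=probes)
        # sealing disc (H = 1): no finite electrical diameter exists, so
        # the 3D domain is carved but the cable stays uncorrected
        r = run(cfg, correct_1d_obstacles=hval < 1.0)
        series.append({"H": float(hval),
                       "before": r.probes[:, 0].copy(),
                       "behind": r.probes[:, 1].copy(),
                       "t": r.t,
                       "peak_before": float(r.probes[:, 0].max()),
                       "peak_behind": float(r.probes[:, 1].max())})
        logger.info("H = %.2f -> before %.4f, behind %.4f uM",
                    hval, series[-1]["peak_before"],
                    series[-1]["peak_behind"])
    return {"h_values": np.asarray(h_values, float), "series": series,
            "probes": probes}
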