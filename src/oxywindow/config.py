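"""YAML run configuration.

Every section is optional: an empty file resolves to the package defaults
(standard muscle/PDMS constants, the 1200 x 1000 x 300 um domain with a
single centred 400 x 200 um window, the standard square-wave protocol).
Unknown keys are rejected by name so typos never silently fall back to a
default. Diffusivities are written in cm^2/s in the file, matching how the
literature quotes them, and converted to um^2/s on load.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import yaml

from .geometry import DomainSpec, WindowLayout, single_window_layout, five_window_layout
from .params import TissueParams, MembraneParams, CM2_PER_S_TO_UM2_PER_S
from .protocols import GasProtocol, NAMED_PROTOCOLS, standard_square_wave
from .solver import SolverSettings
from .metrics import ExtentCriterion


class ConfigError(ValueError):
    """Malformed or inconsistent run configuration."""


@dataclass(frozen=True)
class RunConfig:
    domain: DomainSpec
    layout: WindowLayout
    tissue: TissueParams
    membrane: MembraneParams
    protocol: GasProtocol
    solver: SolverSettings
    criterion: ExtentCriterion
    area_plane_z: float
    challenge_fraction: float
    probes: tuple[tuple[float, float, float], ...]
    output_dir: str
    digest: str = ""


def _take(section: dict, known: dict, name: str) -> dict:
    if section is None:
        section = {}
    if not isinstance(section, dict):
        raise ConfigError(f"section '{name}' must be a mapping")
    unknown = set(section) - set(known)
    if unknown:
        raise ConfigError(f"unknown key(s) in '{name}': {sorted(unknown)}")
    out = dict(known)
    out.update(section)
    return out


_DOMAIN = {"Lx": 1200.0, "Ly": 1000.0, "Lz_tissue": 300.0, "h_pdms": 25.0, "dx": 5.0}
_LAYOUT = {"mode": "single", "window_length": 400.0, "window_width": 200.0,
           "pitch": None, "count": 5}
_TISSUE = {"D": 2.41e-5, "k": 3.89e-5, "M0": 1.57e-4, "P50": 0.5, "P0": 48.0, "K": 30.0}
_MEMBRANE = {"D": 3.40e-5, "k": 1.32e-5}
_PROTOCOL = {"name": None, "segments": None, "pressure": 760.0, "vapor_correction": False}
_SOLVER = {"dt": None, "safety_factor": 0.9, "steady_tol": 1e-3, "max_time": 60.0,
           "check_every": 25, "use_numba": True}
_METRICS = {"threshold": ExtentCriterion().threshold, "area_plane_z": 75.0}
_RUN = {"challenge_fraction": 0.02, "probes": None, "output_dir": "oxywindow_out"}

_SECTIONS = ("domain", "layout", "tissue", "membrane", "protocol", "solver", "metrics", "run")


def resolve_config(raw: dict | None) -> RunConfig:
    """Turn a parsed YAML mapping into a fully validated RunConfig."""
    raw = raw or {}
    if not isinstance(raw, dict):
        raise ConfigError("top level of the config must be a mapping")
    unknown = set(raw) - set(_SECTIONS)
    if unknown:
        raise ConfigError(f"unknown top-level section(s): {sorted(unknown)}")

    dom = _take(raw.get("domain"), _DOMAIN, "domain")
    spec = DomainSpec(**{k: float(v) for k, v in dom.items()})

    lay = _take(raw.get("layout"), _LAYOUT, "layout")
    if lay["mode"] == "single":
        layout = single_window_layout(spec, lay["window_length"], lay["window_width"])
    elif lay["mode"] == "five":
        if lay["pitch"] is None:
            raise ConfigError("layout.pitch is required for mode 'five' (no standard value)")
        layout = five_window_layout(
            spec, float(lay["pitch"]), lay["window_length"], lay["window_width"],
            count=int(lay["count"]),
        )
    else:
        raise ConfigError(f"layout.mode must be 'single' or 'five', got {lay['mode']!r}")

    tis = _take(raw.get("tissue"), _TISSUE, "tissue")
    tissue = TissueParams(
        D=float(tis["D"]) * CM2_PER_S_TO_UM2_PER_S, k=float(tis["k"]), M0=float(tis["M0"]),
        P50=float(tis["P50"]), P0=float(tis["P0"]), K=float(tis["K"]),
    )

    mem = _take(raw.get("membrane"), _MEMBRANE, "membrane")
    membrane = MembraneParams(
        D_prime=float(mem["D"]) * CM2_PER_S_TO_UM2_PER_S, k_prime=float(mem["k"]),
        thickness=spec.h_pdms if spec.h_pdms > 0 else 25.0,
    )

    pro = _take(raw.get("protocol"), _PROTOCOL, "protocol")
    if pro["segments"] is not None:
        protocol = GasProtocol(
            tuple((float(d), float(f)) for d, f in pro["segments"]),
            float(pro["pressure"]), bool(pro["vapor_correction"]),
        )
    else:
        name = pro["name"] or "standard_square_wave"
        if name not in NAMED_PROTOCOLS:
            raise ConfigError(
                f"unknown protocol name {name!r}; available: {sorted(NAMED_PROTOCOLS)}"
            )
        protocol = NAMED_PROTOCOLS[name](float(pro["pressure"]), bool(pro["vapor_correction"]))

    sol = _take(raw.get("solver"), _SOLVER, "solver")
    dt = sol["dt"]
    if isinstance(dt, str):
        if dt != "auto":
            raise ConfigError("solver.dt must be a number or 'auto'")
        dt = None
    settings = SolverSettings(
        dt=dt, safety_factor=float(sol["safety_factor"]), steady_tol=float(sol["steady_tol"]),
        max_time=float(sol["max_time"]), check_every=int(sol["check_every"]),
        use_numba=bool(sol["use_numba"]),
    )

    met = _take(raw.get("metrics"), _METRICS, "metrics")
    criterion = ExtentCriterion(float(met["threshold"]))

    run = _take(raw.get("run"), _RUN, "run")
    frac = float(run["challenge_fraction"])
    if not 0 <= frac <= 1:
        raise ConfigError("run.challenge_fraction must be within [0, 1]")
    if run["probes"] is None:
        # default probes: over the window centre at 25/50/75/100 um below the tissue surface
        cx, cy, _, _ = layout.rectangles[0]
        probes = tuple((cx, cy, spec.h_pdms + d) for d in (25.0, 50.0, 75.0, 100.0))
    else:
        probes = tuple(tuple(float(c) for c in p) for p in run["probes"])

    cfg = RunConfig(
        domain=spec, layout=layout, tissue=tissue, membrane=membrane, protocol=protocol,
        solver=settings, criterion=criterion, area_plane_z=float(met["area_plane_z"]),
        challenge_fraction=frac, probes=probes, output_dir=str(run["output_dir"]),
    )
    digest = hashlib.sha256(
        yaml.safe_dump(dump_config(cfg), sort_keys=True).encode()
    ).hexdigest()[:16]
    object.__setattr__(cfg, "digest", digest)
    return cfg


def load_config(path) -> RunConfig:
    """Parse and resolve a YAML config file; parse errors carry the line."""
    with open(path) as fh:
        try:
            raw = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse {path}: {exc}") from exc
    return resolve_config(raw)


def dump_config(cfg: RunConfig) -> dict:
    """Normalised plain-dict form of a RunConfig (round-trips through
    resolve_config)."""
    spec, lay = cfg.domain, cfg.layout
    rects = lay.rectangles
    lx, ly = rects[0][2], rects[0][3]
    if len(rects) == 1:
        layout = {"mode": "single", "window_length": lx, "window_width": ly,
                  "pitch": None, "count": 5}
    else:
        layout = {"mode": "five", "window_length": lx, "window_width": ly,
                  "pitch": rects[1][0] - rects[0][0], "count": len(rects)}
    return {
        "domain": {"Lx": spec.Lx, "Ly": spec.Ly, "Lz_tissue": spec.Lz_tissue,
                   "h_pdms": spec.h_pdms, "dx": spec.dx},
        "layout": layout,
        "tissue": {"D": cfg.tissue.D / CM2_PER_S_TO_UM2_PER_S, "k": cfg.tissue.k,
                   "M0": cfg.tissue.M0, "P50": cfg.tissue.P50, "P0": cfg.tissue.P0,
                   "K": cfg.tissue.K},
        "membrane": {"D": cfg.membrane.D_prime / CM2_PER_S_TO_UM2_PER_S,
                     "k": cfg.membrane.k_prime},
        "protocol": {"name": None, "segments": [list(s) for s in cfg.protocol.segments],
                     "pressure": cfg.protocol.pressure,
                     "vapor_correction": cfg.protocol.vapor_correction},
        "solver": {"dt": cfg.solver.dt, "safety_factor": cfg.solver.safety_factor,
                   "steady_tol": cfg.solver.steady_tol, "max_time": cfg.solver.max_time,
                   "check_every": cfg.solver.check_every, "use_numba": cfg.solver.use_numba},
        "metrics": {"threshold": cfg.criterion.threshold, "area_plane_z": cfg.area_plane_z},
        "run": {"challenge_fraction": cfg.challenge_fraction,
                "probes": [list(p) for p in cfg.probes], "output_dir": cfg.output_dir},
    }
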