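"""Run configuration, fixtures, and reproducibility manifests.

Configs are YAML with a strict schema (unknown keys rejected); defaults follow
the engines' printed choices (a_grid = 0.15*xi, u_thresh = 0.05).  Fixture
generation writes the standard obstacle inventory — the four rhombi combining
half-widths/heights 0.9 and 1.2 mm, the two staggered-obstacle configurations,
and the lattice-engine defaults — plus miniature (all dimensions / 4) variants
for fast checks.  A RunManifest records parameters, seeds and output checksums
so that stochastic runs are reproducible bit for bit.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from .environments import (
    Environment,
    make_rhombus,
    make_two_obstacle_config,
)
from .errors import ConfigError

__all__ = ["FkppConfig", "EikonalConfig", "EdenRunConfig", "RunConfig",
           "load_config", "make_fixtures", "RunManifest"]

_RHOMBI_MM = [(0.9, 0.9), (0.9, 1.2), (1.2, 0.9), (1.2, 1.2)]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class FkppConfig(_Strict):
    D_eff: float = 0.0144  # mm^2/h
    k_hat: float = 0.7  # 1/h
    u_thresh: float = 0.05
    a_grid: Optional[float] = None  # default 0.15*sqrt(D_eff/k_hat)
    rtol: float = 1e-6
    atol: float = 1e-6
    t_end: Optional[float] = None  # h


class EikonalConfig(_Strict):
    v: float = 0.2  # mm/h
    a_eik: Optional[float] = None  # default w_half/100
    y0_front: float = 0.0
    levels: list[float] = []


class EdenRunConfig(_Strict):
    W: int = 600
    R: float = 80.0
    config: Literal["single", "two-obstacle", "none"] = "single"
    seed: int = 0
    stop_row: Optional[int] = None


class RunConfig(_Strict):
    engine: Literal["eikonal", "fkpp", "eden"]
    environment: Optional[str] = None  # path to an environment JSON
    fkpp: FkppConfig = FkppConfig()
    eikonal: EikonalConfig = EikonalConfig()
    eden: EdenRunConfig = EdenRunConfig()

    def resolved(self) -> "RunConfig":
        """Fill derived defaults (a_grid from D/k)."""
        cfg = self.model_copy(deep=True)
        if cfg.fkpp.a_grid is None:
            cfg.fkpp.a_grid = 0.15 * (cfg.fkpp.D_eff / cfg.fkpp.k_hat) ** 0.5
        return cfg


def load_config(path) -> RunConfig:
    """Load and validate a YAML run config; unknown keys are rejected."""
    p = Path(path)
    if not p.exists():
        raise ConfigError(f"config file not found: {p}")
    with open(p) as fh:
        raw = yaml.safe_load(fh) or {}
    try:
        return RunConfig(**raw).resolved()
    except ValidationError as e:
        keys = "; ".join(
            ".".join(str(x) for x in err["loc"]) + f": {err['msg']}" for err in e.errors()
        )
        raise ConfigError(f"invalid config {p}: {keys}") from e


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.model_dump(), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def _rhombus_env(w_half: float, h_half: float, name: str) -> Environment:
    Lx = 2 * (w_half + 5.0 * w_half)
    cy = 2.0 + h_half
    Ly = cy + 10.0 * w_half + 2.0
    return Environment(
        Lx, Ly, (make_rhombus(w_half, h_half, (Lx / 2.0, cy)),),
        {"config": name, "w_half_mm": w_half, "h_half_mm": h_half},
    )


def make_fixtures(outdir) -> dict[str, Path]:
    """Write the standard obstacle inventory as environment JSON files.

    Four rhombi (w, h half-sizes in {0.9, 1.2} mm), the two-rhombus PDE
    configuration (2 mm / 2 mm offsets), the two-disk lattice configuration
    (5/3 R, 5/2 R offsets), a single-disk lattice default, and miniature
    (scale 1/4) variants of each.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    envs: dict[str, Environment] = {}
    for w, h in _RHOMBI_MM:
        envs[f"rhombus_w{w}_h{h}"] = _rhombus_env(w, h, f"rhombus_w{w}_h{h}")
    envs["two_obstacle_pde"] = make_two_obstacle_config("pde")
    envs["two_obstacle_eden"] = make_two_obstacle_config("eden", R=80.0, W=600.0)
    eden_single = make_two_obstacle_config("eden", R=80.0, W=600.0)
    envs["eden_single"] = Environment(
        eden_single.Lx, eden_single.Ly, eden_single.obstacles[:1],
        {"config": "eden-single", "R": 80.0, "W": 600.0},
    )
    for name in list(envs):
        envs[f"{name}_mini"] = envs[name].scaled(0.25)
    paths = {}
    for name, env in envs.items():
        p = outdir / f"{name}.json"
        env.to_json(p)
        paths[name] = p
    return paths


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class RunManifest:
    """Inventory of a run: engine, parameters, seeds, outputs with checksums."""

    def __init__(self, engine: str, parameters: dict, seed: int | None = None,
                 environment: str | None = None):
        try:
            code_version = version("rangefront")
        except PackageNotFoundError:
            code_version = "unknown"
        self.payload = {
            "engine": engine,
            "parameters": parameters,
            "seed": seed,
            "environment": environment,
            "code_version": code_version,
            "created": datetime.datetime.now(datetime.timezone.utc).isoformat(),
            "outputs": {},
        }

    def add_output(self, path) -> None:
        p = Path(path)
        self.payload["outputs"][p.name] = {"sha256": _sha256(p), "bytes": p.stat().st_size}

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.payload, fh, indent=1, default=str)
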