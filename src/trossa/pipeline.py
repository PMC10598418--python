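"""End-to-end pipeline: validate → rates → deterrent effect → scenarios.

Reads a trossa table, writes a validation report, an effort-standardised
depth rate table, a deterrent-effect table and (when a published-style rate
table plus a landings series are supplied) a depth-restriction scenario
table, together with a manifest recording the seed and a configuration hash
so any run can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import reference
from .errors import StageError, TrossaError
from .leb import BootstrapConfig, effect_table, effects_to_frame
from .rates import RateTable, depth_binned_rates
from .records import (
    DEFAULT_SPECIES_GROUPS,
    FleetDataset,
    load_species_groups,
    read_trossa_table,
    validate_dataset,
    write_trossa_table,
)
from .scenarios import LandingsSeries, ScenarioConstants, scenario_table
from .synthetic import FleetConfig, generate_fleet

logger = logging.getLogger(__name__)

DEFAULT_GROUPS = list(DEFAULT_SPECIES_GROUPS) + ["lumpfish"]
DEFAULT_SCENARIO_DEPTHS = (10.0, 20.0, 30.0, 40.0, 50.0)


@dataclass
class PipelineConfig:
    """Paths and settings of one end-to-end run."""

    data: Path
    out_dir: Path
    rates: Path | None = None  # published-style rate table for scenarios
    landings: Path | None = None
    groups: Path | None = None  # YAML species groups; default groups if None
    scenario_depths: tuple[float, ...] = DEFAULT_SCENARIO_DEPTHS
    n_iter: int = 10_000
    depth_sd: float = 5.0
    seed: int = 0
    observer_only: bool = False
    redistribution: str = "equal"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        base = Path(path).parent
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}

        def p(key):
            return (base / raw[key]) if key in raw and raw[key] else None

        return cls(
            data=p("data"),
            out_dir=base / raw.get("out_dir", "out"),
            rates=p("rates"),
            landings=p("landings"),
            groups=p("groups"),
            scenario_depths=tuple(raw.get("scenario_depths", DEFAULT_SCENARIO_DEPTHS)),
            n_iter=int(raw.get("n_iter", 10_000)),
            depth_sd=float(raw.get("depth_sd", 5.0)),
            seed=int(raw.get("seed", 0)),
            observer_only=bool(raw.get("observer_only", False)),
            redistribution=str(raw.get("redistribution", "equal")),
            log_level=str(raw.get("log_level", "INFO")),
        )


def _config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(
        {k: str(v) for k, v in dataclasses.asdict(cfg).items()}, sort_keys=True
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_all(cfg: PipelineConfig) -> dict[str, Path]:
    """Run every stage; returns the mapping of artifact name to path.

    On stage failure a ``FAILED`` marker naming the stage is written next to
    any partial outputs and :class:`StageError` is raised.
    """
    logging.basicConfig(level=cfg.log_level)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    stage = "data"
    t0 = time.time()
    try:
        if cfg.data is None or not Path(cfg.data).exists():
            raise TrossaError(f"data file not found: {cfg.data}")
        dataset = read_trossa_table(cfg.data)
        if cfg.groups is not None:
            dataset.species_groups = load_species_groups(cfg.groups)
        if cfg.observer_only:
            dataset = dataset.subset(lambda r: bool(r.observer_onboard))
        logger.info("data: %d records, %d trips, %d with deterrent",
                    len(dataset), dataset.n_trips, dataset.n_leb)

        stage = "validate"
        report = validate_dataset(dataset)
        artifacts["validation"] = out / "validation.json"
        artifacts["validation"].write_text(
            json.dumps(
                {
                    "n_records": report.n_records,
                    "n_trips": report.n_trips,
                    "n_leb": report.n_leb,
                    "ok": report.ok,
                    "violations": [dataclasses.asdict(v) for v in report.violations],
                    "flags": [dataclasses.asdict(v) for v in report.flags],
                },
                indent=2,
            )
        )

        stage = "rates"
        empirical = depth_binned_rates(dataset)
        artifacts["rates"] = out / "rates.csv"
        empirical.to_csv(artifacts["rates"])

        stage = "effects"
        groups = list(dataset.species_groups) + ["lumpfish"]
        bcfg = BootstrapConfig(n_iter=cfg.n_iter, depth_sd=cfg.depth_sd, seed=cfg.seed)
        effects = effect_table(dataset, groups, bcfg)
        artifacts["effects"] = out / "effects.csv"
        effects_to_frame(effects).to_csv(artifacts["effects"], index=False)

        stage = "scenarios"
        if cfg.rates is not None and cfg.landings is not None:
            rate_tab = RateTable.from_csv(cfg.rates)
            landings = LandingsSeries.from_csv(cfg.landings)
            constants = ScenarioConstants(redistribution=cfg.redistribution)
            table = scenario_table(landings, rate_tab, cfg.scenario_depths, constants)
            artifacts["scenarios"] = out / "scenarios.csv"
            table.to_csv(artifacts["scenarios"], index=False)
        else:
            logger.info("scenarios: skipped (no rate table / landings supplied)")

        stage = "manifest"
        artifacts["manifest"] = out / "manifest.json"
        artifacts["manifest"].write_text(
            json.dumps(
                {
                    "seed": cfg.seed,
                    "config_hash": _config_hash(cfg),
                    "config": {k: str(v) for k, v in dataclasses.asdict(cfg).items()},
                    "artifacts": {k: str(v) for k, v in artifacts.items()},
                    "elapsed_s": round(time.time() - t0, 3),
                    "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
                },
                indent=2,
            )
        )
    except Exception as exc:
        (out / "FAILED").write_text(f"{stage}: {exc}\n")
        raise StageError(stage, str(exc)) from exc
    return artifacts


def make_demo(seed: int = 0, workspace: str | Path = "demo") -> dict[str, Path]:
    """Build a self-contained demo workspace.

    Writes a synthetic fleet (seeded), the published depth-specific rate
    table (including landings proportions and per-bin annual bycatch), a
    landings file carrying the 2014–2021 mean tonnage, default species
    groups, and a pipeline config wired to them.  The rate/landings files are
    printed constants: they are identical for every seed, only the synthetic
    fleet varies.
    """
    ws = Path(workspace)
    ws.mkdir(parents=True, exist_ok=True)
    paths = {
        "fleet": ws / "fleet.csv",
        "rates": ws / "rates.csv",
        "landings": ws / "landings.csv",
        "groups": ws / "groups.yml",
        "config": ws / "config.yml",
    }
    dataset, _ = generate_fleet(FleetConfig(seed=seed))
    write_trossa_table(dataset, paths["fleet"])
    reference.reference_rate_table().to_csv(paths["rates"])
    LandingsSeries(
        tons={"2014-2021 mean": reference.MEAN_ANNUAL_LANDINGS_TONS}
    ).to_csv(paths["landings"])
    with open(paths["groups"], "w") as fh:
        yaml.safe_dump(DEFAULT_SPECIES_GROUPS, fh)
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(
            {
                "data": "fleet.csv",
                "rates": "rates.csv",
                "landings": "landings.csv",
                "groups": "groups.yml",
                "out_dir": "out",
                "seed": seed,
            },
            fh,
        )
    return paths
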