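"""Run configuration: a single structured file bundling all parameter blocks.

YAML layout (every key optional, defaults shown by ``awpm config
--show-defaults``)::

    weather:
      source: synthetic        # or: file
      path: weather.csv        # when source is file
      seed: 1
    soil:     {ms: 0.46, mfc: 0.33, ...}
    crop:     {tb: 8.0, t0: 25.0, ...}
    et:       {kc_mx: 1.2, lai_ref: 3.0, k_beer: 0.5, p: 0.5}
    scenario:
      gwd0: 150
      theta0: 0.3
      start: 2007-04-20
      end: 2007-09-24
      irrigation:
        - {date: 2007-06-26, mm: 97.5}
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass, field, replace

import yaml

from awpm.crop import MAIZE, CropParams
from awpm.et import DEFAULT_ET, ETCoefficients
from awpm.simulator import BASE_IRRIGATION_SCHEDULE, DEFAULT_YEAR, ScenarioSpec
from awpm.soil import LOAM, SoilHydraulicParams
from awpm.weather import HETAO, ClimateNormals

__all__ = ["RunConfig", "load_config", "default_config", "dump_defaults"]


@dataclass(frozen=True)
class RunConfig:
    """Everything needed for one deterministic season run."""

    scenario: ScenarioSpec
    soil: SoilHydraulicParams = LOAM
    crop: CropParams = MAIZE
    et: ETCoefficients = DEFAULT_ET
    site: ClimateNormals = HETAO

    def parameter_blocks(self) -> dict[str, object]:
        return {"soil": self.soil, "crop": self.crop, "et": self.et}

    def with_param(self, name: str, value: float) -> "RunConfig":
        """Return a copy with one named soil/crop/et parameter replaced.

        *name* may be qualified (``soil.ks``) or bare (``ks``); a bare name
        must be unambiguous across blocks.
        """
        if "." in name:
            block, attr = name.split(".", 1)
            blocks = {block: getattr(self, block)}
        else:
            attr = name
            blocks = self.parameter_blocks()
        hits = [b for b, obj in blocks.items()
                if attr in {f.name for f in dataclasses.fields(obj)}]
        if not hits:
            raise KeyError(f"unknown parameter {name!r}")
        if len(hits) > 1:
            raise KeyError(f"ambiguous parameter {name!r}: in {hits}")
        block = hits[0]
        return replace(self, **{block: replace(getattr(self, block),
                                               **{attr: value})})

    def get_param(self, name: str) -> float:
        if "." in name:
            block, attr = name.split(".", 1)
            obj = getattr(self, block, None)
            if obj is None or not attr_in(obj, attr):
                raise KeyError(f"unknown parameter {name!r}")
            return getattr(obj, attr)
        for obj in self.parameter_blocks().values():
            if attr_in(obj, name):
                return getattr(obj, name)
        raise KeyError(f"unknown parameter {name!r}")


def attr_in(obj, name: str) -> bool:
    return name in {f.name for f in dataclasses.fields(obj)}


def default_config(gwd0: float = 150.0, seed: int = 1) -> RunConfig:
    irrigation = tuple((dt.date(DEFAULT_YEAR, m, d), depth)
                       for (m, d), depth in BASE_IRRIGATION_SCHEDULE)
    return RunConfig(scenario=ScenarioSpec(gwd0=gwd0, irrigation=irrigation,
                                           seed=seed))


def _parse_date(value) -> dt.date:
    if isinstance(value, dt.date):
        return value
    return dt.date.fromisoformat(str(value))


def load_config(path) -> RunConfig:
    """Build a RunConfig from a YAML file, falling back to defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    base = default_config()

    soil = replace(base.soil, **raw.get("soil", {}))
    crop = replace(base.crop, **raw.get("crop", {}))
    et = replace(base.et, **raw.get("et", {}))

    sc = raw.get("scenario", {})
    spec = base.scenario
    kwargs = {}
    if "gwd0" in sc:
        kwargs["gwd0"] = float(sc["gwd0"])
    if "theta0" in sc:
        kwargs["theta0"] = float(sc["theta0"])
    if "start" in sc:
        kwargs["start"] = _parse_date(sc["start"])
    if "end" in sc:
        kwargs["end"] = _parse_date(sc["end"])
    if "irrigation" in sc:
        kwargs["irrigation"] = tuple(
            (_parse_date(ev["date"]), float(ev["mm"]))
            for ev in sc["irrigation"]
        )

    wx = raw.get("weather", {})
    if wx.get("source", "synthetic") == "file":
        kwargs["weather"] = wx["path"]
    if "seed" in wx:
        kwargs["seed"] = int(wx["seed"])
    spec = replace(spec, **kwargs)

    return RunConfig(scenario=spec, soil=soil, crop=crop, et=et)


def dump_defaults() -> str:
    """YAML text of the full default configuration."""
    cfg = default_config()
    doc = {
        "weather": {"source": "synthetic", "seed": cfg.scenario.seed},
        "soil": dataclasses.asdict(cfg.soil),
        "crop": dataclasses.asdict(cfg.crop),
        "et": dataclasses.asdict(cfg.et),
        "scenario": {
            "gwd0": cfg.scenario.gwd0,
            "theta0": cfg.scenario.theta0,
            "start": cfg.scenario.start.isoformat(),
            "end": cfg.scenario.end.isoformat(),
            "irrigation": [{"date": d.isoformat(), "mm": mm}
                           for d, mm in cfg.scenario.irrigation],
        },
    }
    return yaml.safe_dump(doc, sort_keys=False)
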