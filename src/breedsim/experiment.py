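"""Replicated scheme x GEI experiment grids.

Each replicate runs one burn-in per GEI level (founder genome and
additive effects are shared across GEI levels; only the interaction
effects are re-scaled) and branches every requested scheme from an
identical copy of the burn-in state, so within a replicate all schemes
start from a bit-identical base population.  Results are written as a
tidy CSV (one row per scheme x GEI x replicate x year), an aggregate CSV
of means and standard errors over replicates, and a JSON manifest
recording the configuration and seeds.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .genome import GenomeSpec
from .metrics import genetic_gain
from .schemes import (SCHEMES, BurninConfig, SchemeConfig, run_burnin,
                      run_scheme)
from .trait import TraitSpec

__all__ = [
    "ExperimentConfig",
    "run_experiment",
    "run_replicate",
    "aggregate",
    "load_config",
]


@dataclass
class ExperimentConfig:
    """A replicated grid of schemes and GEI levels."""

    schemes: tuple = SCHEMES
    gei_levels: tuple = (0.0, 4.0, 8.0)
    n_replicates: int = 100
    years: int = 30
    burnin_years: int = 40
    master_seed: int = 1
    scale: float = 1.0      # shrinks per-family progeny counts only
    out_dir: str | None = None
    genome: GenomeSpec = field(default_factory=GenomeSpec)
    burnin: BurninConfig = field(default_factory=BurninConfig)
    scheme_template: SchemeConfig = field(default_factory=SchemeConfig)

    def __post_init__(self):
        self.schemes = tuple(self.schemes)
        self.gei_levels = tuple(float(g) for g in self.gei_levels)
        unknown = set(self.schemes) - set(SCHEMES)
        if unknown:
            raise ValueError(f"unknown schemes: {sorted(unknown)}")
        if self.n_replicates < 1 or self.years < 0:
            raise ValueError("n_replicates must be >= 1 and years >= 0")

    def burnin_config(self) -> BurninConfig:
        cfg = self.burnin.scaled(self.scale) if self.scale != 1.0 else self.burnin
        return cfg if cfg.years == self.burnin_years else \
            type(cfg)(**{**asdict(cfg), "years": self.burnin_years})

    def scheme_config(self, scheme: str) -> SchemeConfig:
        cfg = self.scheme_template
        if self.scale != 1.0:
            cfg = cfg.scaled(self.scale)
        return type(cfg)(**{**asdict(cfg), "scheme": scheme})

    def digest(self) -> str:
        blob = json.dumps(
            {"schemes": self.schemes, "gei": self.gei_levels,
             "reps": self.n_replicates, "years": self.years,
             "burnin_years": self.burnin_years, "seed": self.master_seed,
             "scale": self.scale, "genome": asdict(self.genome),
             "burnin": asdict(self.burnin),
             "scheme": asdict(self.scheme_template)},
            sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


_GEI_CODE = {0.0: 0, 4.0: 1, 8.0: 2}


def _seed_for(cfg: ExperimentConfig, replicate: int, gei: float,
              scheme: str | None) -> np.random.SeedSequence:
    """Deterministic stream key; identical burn-in for all schemes."""
    gei_code = _GEI_CODE.get(gei, int(round(gei)) + 100)
    scheme_code = 0 if scheme is None else SCHEMES.index(scheme) + 1
    return np.random.SeedSequence(
        [cfg.master_seed, replicate, gei_code, scheme_code])


def run_replicate(cfg: ExperimentConfig, replicate: int) -> pd.DataFrame:
    """All scheme x GEI cells of one replicate, from shared burn-ins."""
    frames = []
    for gei in cfg.gei_levels:
        tspec = TraitSpec(gei_variance=gei)
        state = run_burnin(cfg.genome, tspec, cfg.burnin_config(),
                           _seed_for(cfg, replicate, gei, None))
        for scheme in cfg.schemes:
            rows = run_scheme(state, cfg.scheme_config(scheme), cfg.years,
                              _seed_for(cfg, replicate, gei, scheme))
            df = pd.DataFrame(rows)
            df.insert(0, "replicate", replicate)
            frames.append(df)
    return pd.concat(frames, ignore_index=True)


def run_experiment(cfg: ExperimentConfig, progress=None) -> dict:
    """Run the full grid; returns the tidy and aggregate DataFrames.

    With ``cfg.out_dir`` set, per-replicate part files allow interrupted
    runs to resume: parts whose manifest digest matches are reused.
    """
    out = cfg.out_dir
    digest = cfg.digest()
    parts = []
    for rep in range(cfg.n_replicates):
        part_path = None
        if out is not None:
            os.makedirs(out, exist_ok=True)
            part_path = os.path.join(out, f"part_rep{rep:03d}_{digest}.csv")
        if part_path is not None and os.path.exists(part_path):
            part = pd.read_csv(part_path, float_precision="round_trip")
        else:
            part = run_replicate(cfg, rep)
            if part_path is not None:
                part.to_csv(part_path, index=False)
        parts.append(part)
        if progress is not None:
            progress(rep)
    tidy = pd.concat(parts, ignore_index=True)
    summary = aggregate(tidy)
    if out is not None:
        tidy.to_csv(os.path.join(out, "tidy.csv"), index=False)
        summary["gain"].to_csv(os.path.join(out, "aggregate_gain.csv"), index=False)
        summary["yearly"].to_csv(os.path.join(out, "aggregate_yearly.csv"), index=False)
        summary["alleles"].to_csv(os.path.join(out, "aggregate_alleles.csv"), index=False)
        with open(os.path.join(out, "manifest.json"), "w") as fh:
            json.dump({"digest": digest, "master_seed": cfg.master_seed,
                       "schemes": cfg.schemes, "gei_levels": cfg.gei_levels,
                       "n_replicates": cfg.n_replicates, "years": cfg.years,
                       "scale": cfg.scale}, fh, indent=2)
    return {"tidy": tidy, **summary}


def replicate_gains(tidy: pd.DataFrame, horizon: int) -> pd.DataFrame:
    """Per-replicate OLS gain slopes over years 0..horizon."""
    rows = []
    for (scheme, gei, rep), grp in tidy.groupby(
            ["scheme", "gei_variance", "replicate"]):
        grp = grp.sort_values("year")
        if grp["year"].max() < horizon:
            continue
        est = genetic_gain(grp["mean_gv_centered"].to_numpy(), horizon)
        rows.append({"scheme": scheme, "gei_variance": gei, "replicate": rep,
                     "horizon": horizon, "slope": est.slope})
    return pd.DataFrame(rows)


def aggregate(tidy: pd.DataFrame) -> dict:
    """Summary tables over replicates.

    ``gain``: mean slope with its standard error per scheme x GEI x
    horizon, plus the relative advantage (%) over the 3-year and 5-year
    schemes where those are present.  ``yearly``: per-year means and
    standard errors of the tracked indicators.  ``alleles``: favorable
    alleles lost/fixed at the two horizons.
    """
    horizons = [h for h in (15, 30) if tidy["year"].max() >= h]
    gains = pd.concat([replicate_gains(tidy, h) for h in horizons],
                      ignore_index=True) if horizons else pd.DataFrame()
    gain_rows = []
    if not gains.empty:
        g = gains.groupby(["scheme", "gei_variance", "horizon"])["slope"]
        stats = g.agg(["mean", "sem", "count"]).reset_index()
        for _, row in stats.iterrows():
            rec = {"scheme": row["scheme"], "gei_variance": row["gei_variance"],
                   "horizon": int(row["horizon"]),
                   "gain_per_year": row["mean"],
                   "sem": row["sem"] if row["count"] > 1 else np.nan,
                   "n_replicates": int(row["count"])}
            for ref in ("3-year", "5-year"):
                m = stats[(stats["scheme"] == ref)
                          & (stats["gei_variance"] == row["gei_variance"])
                          & (stats["horizon"] == row["horizon"])]
                rec[f"vs_{ref}_pct"] = (
                    100.0 * (row["mean"] / m["mean"].iloc[0] - 1.0)
                    if len(m) else np.nan)
            gain_rows.append(rec)
    gain = pd.DataFrame(gain_rows)

    num_cols = ["mean_gv_centered", "var_gv", "accuracy", "pct_fixed",
                "pct_lost", "pct_nearly_fixed", "pct_rare"]
    yearly = (tidy.groupby(["scheme", "gei_variance", "year"])[num_cols]
              .agg(["mean", "sem"]))
    yearly.columns = ["_".join(c) for c in yearly.columns]
    yearly = yearly.reset_index()

    allele_rows = tidy[tidy["year"].isin([y for y in (15, 30)
                                          if tidy["year"].max() >= y])]
    alleles = (allele_rows.groupby(["scheme", "gei_variance", "year"])
               [["pct_lost", "pct_fixed"]].mean().reset_index())
    return {"gain": gain, "yearly": yearly, "alleles": alleles}


def load_config(path) -> ExperimentConfig:
    """Build an ExperimentConfig from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = {}
    for key in ("schemes", "gei_levels", "n_replicates", "years",
                "burnin_years", "master_seed", "scale", "out_dir"):
        if key in raw:
            kwargs[key] = raw[key]
    if "genome" in raw:
        kwargs["genome"] = GenomeSpec(**raw["genome"])
    if "burnin" in raw:
        kwargs["burnin"] = BurninConfig(**raw["burnin"])
    if "scheme" in raw:
        kwargs["scheme_template"] = SchemeConfig(**raw["scheme"])
    return ExperimentConfig(**kwargs)
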