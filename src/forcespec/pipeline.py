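"""End-to-end condition runs: configuration, orchestration, reporting.

A *condition* is one probe/receptor combination measured as a DFS dataset.
``run_condition`` takes a structured config (YAML/JSON), obtains events
either from a simulation block or from an event-table CSV, fits the FNdY
model, derives the thermodynamics, and writes a deterministic report JSON
(plus a band CSV and a run manifest). ``compare_conditions`` feeds several
condition reports into the cooperativity ledger.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dfs import (
    DFSDataset,
    assemble_dfs,
    bands,
    cooperativity_ledger,
    derive_thermo,
    fit_fndy,
)
from .exceptions import ConfigError, InsufficientDataError
from .physics import FNdYModel, ThermoConstants, ThermoResult
from .simulate import BondTruth, gen_dfs_dataset

__all__ = ["load_config", "run_condition", "compare_conditions"]


def load_config(path) -> dict:
    """Load a YAML (or JSON) run configuration."""
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ConfigError(f"config {path} did not parse to a mapping")
    return cfg


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _dataset_from_config(cfg: dict, seed: int) -> tuple[DFSDataset, dict]:
    if "simulate" in cfg:
        sim = cfg["simulate"]
        tr = sim.get("truth", {})
        truth = BondTruth(
            model=FNdYModel(
                F_eq=float(tr.get("F_eq_pN", 50.0)),
                f_beta=float(tr.get("f_beta_pN", 10.0)),
                k_off_eq=float(tr.get("k_off_eq_per_s", 1e3)),
                k_eff=float(tr.get("k_eff_pN_nm", cfg.get("k_eff_pN_nm", 13.1))),
            )
        )
        ds, truth_rec = gen_dfs_dataset(
            n=int(sim.get("n_events", 500)),
            truth=truth,
            lr_range=tuple(sim.get("lr_range_pN_s", (1e2, 1e6))),
            scatter_sd=float(sim.get("scatter_sd_pN", 10.0)),
            seed=seed,
            mode=sim.get("mode", "gaussian"),
            label=cfg.get("condition", "simulated"),
        )
        provenance = {"kind": "simulation", "truth": truth_rec, "seed": seed}
    elif "events_csv" in cfg:
        path = Path(cfg["events_csv"])
        if not path.exists():
            raise ConfigError(f"event table {path} does not exist")
        from .curves import read_event_table

        events = read_event_table(path)
        ds = assemble_dfs(
            events,
            condition=cfg.get("condition", ""),
            min_events=int(cfg.get("min_events", 30)),
            orientation_gate=bool(cfg.get("orientation_gate", False)),
        )
        provenance = {
            "kind": "event_table",
            "path": str(path),
            "sha256": hashlib.sha256(path.read_bytes()).hexdigest(),
        }
    else:
        raise ConfigError(
            "config must contain a 'simulate' block or an 'events_csv' path"
        )
    return ds, provenance


def run_condition(cfg: dict, seed: int = 0, out_dir=None) -> dict:
    """Execute one condition: events -> FNdY fit -> thermodynamics -> report.

    Returns the report dict; with ``out_dir`` also writes ``report.json``
    (deterministic: no timestamps), ``bands.csv`` and ``manifest.json``.
    """
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a mapping")
    label = str(cfg.get("condition", "condition"))
    tc = ThermoConstants(temperature=float(cfg.get("temperature_K", 297.15)))
    try:
        ds, provenance = _dataset_from_config(cfg, seed)
    except InsufficientDataError as err:
        raise InsufficientDataError(f"[stage: assemble] {err}") from err
    k_eff = float(cfg.get("k_eff_pN_nm", 13.1))
    fit = fit_fndy(
        ds, tc=tc, k_eff=k_eff, min_events=int(cfg.get("min_events", 30))
    )
    thermo = derive_thermo(fit, tc=tc, label=label)
    lr_grid = np.logspace(
        np.log10(ds.loading_rates.min()), np.log10(ds.loading_rates.max()), 40
    )
    try:
        band_table = bands(fit, lr_grid)
    except Exception:
        band_table = None
    report = {
        "condition": label,
        "package_version": __version__,
        "seed": seed,
        "config_hash": _config_hash(cfg),
        "n_events": ds.n,
        "fit": fit.to_dict(),
        "thermo": thermo.to_dict(),
        "provenance": provenance,
        "units": {
            "F_eq": "pN",
            "f_beta": "pN",
            "k_off_eq": "1/s",
            "k_eff": "pN/nm",
            "deltaG_bu": "kcal/mol",
            "Kd": "mol/l",
            "tau_half": "s",
        },
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / f"report_{label}.json").write_text(
            json.dumps(report, indent=1, sort_keys=True, default=str)
        )
        files = [f"report_{label}.json"]
        if band_table is not None:
            band_table.to_csv(out / f"bands_{label}.csv", index=False)
            files.append(f"bands_{label}.csv")
        manifest = {
            "condition": label,
            "created": datetime.datetime.now().isoformat(),
            "seed": seed,
            "config": cfg,
            "config_hash": report["config_hash"],
            "package_version": __version__,
            "outputs": files,
            "warnings": fit.warnings,
        }
        (out / f"manifest_{label}.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True, default=str)
        )
    return report


def _thermo_from_report(report: dict) -> ThermoResult:
    t = report["thermo"]
    return ThermoResult(
        deltaG_bu=float(t["deltaG_bu_kcal_mol"]),
        Kd=float(t["Kd_M"]),
        tau_half=float(t["tau_half_s"]),
        deltaG_sem=float(t["deltaG_sem_kcal_mol"]),
        Kd_sem=float(t["Kd_sem_M"]),
        tau_half_sem=float(t["tau_half_sem_s"]),
        label=report["condition"],
    )


def compare_conditions(reports: list, full_label: str, part_labels: list) -> tuple:
    """Cooperativity ledger across condition reports plus a summary table.

    ``full_label`` names the intact-ligand condition; ``part_labels`` the
    individually measured sites. Returns (ledger, summary DataFrame).
    """
    if len(reports) < 3:
        raise ConfigError("need >= 3 condition reports (full + >= 2 parts)")
    by_label = {r["condition"]: r for r in reports}
    missing = [lab for lab in [full_label, *part_labels] if lab not in by_label]
    if missing:
        raise ConfigError(f"missing condition reports: {missing}")
    full = _thermo_from_report(by_label[full_label])
    parts = [_thermo_from_report(by_label[lab]) for lab in part_labels]
    ledger = cooperativity_ledger(full, parts)
    rows = []
    for lab in [full_label, *part_labels]:
        t = by_label[lab]["thermo"]
        f = by_label[lab]["fit"]
        rows.append(
            {
                "condition": lab,
                "n": by_label[lab]["n_events"],
                "F_eq_pN": f["F_eq_pN"],
                "deltaG_bu_kcal_mol": t["deltaG_bu_kcal_mol"],
                "deltaG_sem": t["deltaG_sem_kcal_mol"],
                "Kd_M": t["Kd_M"],
                "tau_half_s": t["tau_half_s"],
            }
        )
    return ledger, pd.DataFrame(rows)
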