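"""Delimited-text readers/writers, configuration and the pipeline driver.

Two table schemas round-trip through this module:

* snapshot tables — ``cell_id,replicate,condition,value`` (simulated protein
  counts or already-extracted intensities);
* cytometry tables — ``FITC-H,SSC-H,FSC-H,Width,replicate,condition``.

The pipeline driver executes a YAML/JSON-configured sequence of stages
(synthesize, simulate, classify, shape, calibrate) with one master seed and
writes a machine-readable JSON report; identical config + seed give an
identical report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cytometry as cyto
from .modality import ModalityConfig, classify_modality, shape_params
from .rates import (
    RateSet,
    reference_rates,
    apply_scenario,
    named_scenario,
    stationary_condition,
)
from .reactions import build_reduced_model
from .ssa import SnapshotDistribution, sample_snapshot

__all__ = [
    "read_cells",
    "write_snapshot",
    "write_cytometry",
    "load_config",
    "run_pipeline",
    "call_to_dict",
]

log = logging.getLogger("bimodalkit")

SNAPSHOT_COLUMNS = ["cell_id", "replicate", "condition", "value"]
CYTOMETRY_COLUMNS = list(cyto.CHANNELS) + ["replicate", "condition"]


def read_cells(path):
    """Read a snapshot or cytometry table, deciding by header.

    Returns a :class:`SnapshotDistribution` or :class:`CytometryTable`.
    Malformed rows are reported with their (1-based, header-inclusive) line
    numbers.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty file") from None
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    cols = set(df.columns)
    if set(CYTOMETRY_COLUMNS) <= cols:
        bad = df.index[(df[list(cyto.CHANNELS)] <= 0).any(axis=1)]
        if len(bad):
            lines = ", ".join(str(i + 2) for i in bad[:10])
            raise ValueError(f"{path}: non-positive channel values at lines {lines}")
        return cyto.CytometryTable(df[CYTOMETRY_COLUMNS])
    if set(SNAPSHOT_COLUMNS) <= cols:
        bad = df.index[df["value"].isna() | (df["value"] < 0)]
        if len(bad):
            lines = ", ".join(str(i + 2) for i in bad[:10])
            raise ValueError(f"{path}: invalid values at lines {lines}")
        condition = df["condition"].iloc[0]
        kind = "intensity" if "kind" in cols and df["kind"].iloc[0] == "intensity" else "count"
        return SnapshotDistribution(
            values=df["value"].to_numpy(float),
            replicate=df["replicate"].to_numpy(),
            condition=str(condition),
            kind=kind,
        )
    # report the missing columns of whichever schema the header is closest to
    best = max(
        (CYTOMETRY_COLUMNS, SNAPSHOT_COLUMNS),
        key=lambda req: len(cols & set(req)) / len(req),
    )
    missing = [c for c in best if c not in cols]
    if len(missing) < len(best):
        raise ValueError(f"{path}: missing column(s) {missing}")
    raise ValueError(
        f"{path}: header matches neither snapshot {SNAPSHOT_COLUMNS} nor "
        f"cytometry {CYTOMETRY_COLUMNS} schema"
    )


def write_snapshot(snapshot: SnapshotDistribution, path) -> None:
    df = pd.DataFrame(
        {
            "cell_id": np.arange(len(snapshot)),
            "replicate": snapshot.replicate,
            "condition": snapshot.condition,
            "value": snapshot.values,
            "kind": snapshot.kind,
        }
    )
    df.to_csv(path, index=False)


def write_cytometry(table: cyto.CytometryTable, path) -> None:
    table.frame[CYTOMETRY_COLUMNS].to_csv(path, index=False)


def load_config(path) -> dict:
    """Load a YAML (or JSON — YAML is a superset) run configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def resolve_condition(rates: RateSet, scenario: str) -> RateSet:
    """Apply a named scenario, or ``stationary:<f>`` for the phase transition."""
    if scenario.startswith("stationary"):
        _, _, frac = scenario.partition(":")
        return stationary_condition(float(frac) if frac else 1.0, rates)
    return apply_scenario(rates, named_scenario(scenario))


def call_to_dict(call, shapes=None) -> dict:
    """JSON-ready record of a modality call (+ shape parameters if bimodal)."""
    out = {
        "verdict": call.verdict,
        "criteria": {"bic": call.bic_criterion, "peaks": call.peaks_criterion},
        "bic1": call.fit1.bic,
        "bic2": call.fit2.bic,
        "mixture2": {
            "weights": call.fit2.weights.tolist(),
            "means": call.fit2.means.tolist(),
            "sds": call.fit2.sds.tolist(),
        },
        "scale": call.scale,
        "h_convention": call.h_convention,
    }
    if call.is_bimodal:
        out.update(pk1=call.pk1, pk2=call.pk2, pdf1=call.pdf1, pdf2=call.pdf2)
    if shapes is not None:
        out.update(d=shapes.d, h=shapes.h, o=shapes.o)
    return out


KNOWN_STAGES = ("synth", "simulate", "classify", "shape")


def run_pipeline(config: dict, out_dir=None) -> dict:
    """Execute the configured stages and return (and optionally write) a report.

    Config schema::

        seed: 1
        units: minutes
        stages:
          - kind: synth          # generate a named synthetic fixture
            fixture: synthetic_distant_even
          - kind: simulate       # reference-model snapshot
            n_cells: 2000
            scenario: identity   # optional named perturbation
          - kind: classify       # classify a written/loaded table
            input: <path>        # or omit to use the previous stage's output
          - kind: shape
    """
    if "stages" not in config or not isinstance(config["stages"], list):
        raise ValueError("config needs a 'stages' list")
    for stage in config["stages"]:
        if stage.get("kind") not in KNOWN_STAGES:
            raise ValueError(f"unknown stage kind {stage.get('kind')!r}")
    seed = int(config.get("seed", 0))
    mod_cfg = ModalityConfig(**config.get("modality", {}))
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": seed, "units": config.get("units", "minutes"), "stages": []}
    current = None  # last produced values table
    for i, stage in enumerate(config["stages"]):
        kind = stage["kind"]
        record: dict = {"kind": kind}
        log.info("stage %d: %s (seed=%d)", i, kind, seed)
        if kind == "synth":
            name = stage.get("fixture", "synthetic_distant_even")
            spec = cyto.SYNTHETIC_FIXTURES[name]
            if "n_cells" in stage:
                spec = dataclasses.replace(spec, n_cells=int(stage["n_cells"]))
            table = cyto.generate_population(spec, seed=seed + i)
            current = table.intensities()
            record.update(fixture=name, n=len(table))
            if out_dir is not None:
                cyto_path = out_dir / f"stage{i}_{name}.csv"
                write_cytometry(table, cyto_path)
                record["table"] = str(cyto_path)
        elif kind == "simulate":
            rates = reference_rates()
            if "rates" in stage:
                rates = RateSet.from_dict(stage["rates"])
            if "scenario" in stage:
                rates = resolve_condition(rates, stage["scenario"])
            system = build_reduced_model(rates)
            current = sample_snapshot(
                system,
                n_cells=int(stage.get("n_cells", 2000)),
                seed=seed + i,
                condition=stage.get("scenario", "reference"),
            )
            record.update(n=len(current), condition=current.condition)
            if out_dir is not None:
                p = out_dir / f"stage{i}_snapshot.csv"
                write_snapshot(current, p)
                record["table"] = str(p)
        elif kind in ("classify", "shape"):
            if "input" in stage:
                data = read_cells(stage["input"])
                current = data.intensities() if isinstance(data, cyto.CytometryTable) else data
            if current is None:
                raise ValueError(f"stage {i} ({kind}): no input table available")
            call = classify_modality(current.values, kind=current.kind, config=mod_cfg)
            shapes = None
            if kind == "shape":
                if not call.is_bimodal:
                    record["shape_error"] = "distribution not bimodal"
                else:
                    shapes = shape_params(call, current.values, kind=current.kind)
            record.update(condition=current.condition, result=call_to_dict(call, shapes))
        report["stages"].append(record)
    if out_dir is not None:
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    return report
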