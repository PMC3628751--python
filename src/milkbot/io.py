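"""CSV dialects for test-day records, fitted parameters, and truth tables.

Test-day files are comma-delimited with a header row and columns
``lactation_id, herd_id, parity_group, dim, milk_kg`` — one row per milk
weight. Parity accepts aliases ("1" -> P1; "2+", "2plus" or any integer
>= 2 -> P2plus). Parameter files carry one row per fitted lactation with
the four parameters, RMSE, and the closed-form derived metrics, written
at 10 significant digits so they round-trip losslessly.
"""

from __future__ import annotations

import json
import hashlib
import logging
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import model
from .fitting import Lactation, TestDay, normalize_parity
from .model import MilkBotParams

__all__ = [
    "FormatError",
    "TESTDAY_COLUMNS",
    "PARAMS_COLUMNS",
    "read_testday_csv",
    "write_testday_csv",
    "read_params_csv",
    "write_params_csv",
    "write_truth_csv",
    "write_manifest",
    "KG_PER_LB",
]

logger = logging.getLogger(__name__)

TESTDAY_COLUMNS = ["lactation_id", "herd_id", "parity_group", "dim", "milk_kg"]
PARAMS_COLUMNS = [
    "lactation_id", "herd_id", "parity_group",
    "scale", "ramp", "offset", "decay",
    "rmse", "n_tests", "m305", "peak_day", "peak_milk", "persistence", "flags",
]

KG_PER_LB = 0.45359237


class FormatError(ValueError):
    """A file does not conform to the documented CSV dialect."""


def read_testday_csv(
    path,
    *,
    units: str = "kg",
    keep_first_duplicate: bool = False,
) -> list[Lactation]:
    """Read a test-day CSV into Lactation objects.

    Rows are grouped by lactation_id and sorted by DIM. Malformed rows
    (non-numeric or out-of-range dim/milk, bad parity) are skipped with a
    line-numbered log message. Duplicate (lactation, dim) pairs raise by
    default; ``keep_first_duplicate=True`` keeps the first and logs the
    rest. ``units="lb"`` converts milk weights to kg on read.
    """
    if units not in {"kg", "lb"}:
        raise ValueError(f"units must be 'kg' or 'lb', got {units!r}")
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    missing = [c for c in TESTDAY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: missing required column(s) {', '.join(missing)}"
        )
    factor = KG_PER_LB if units == "lb" else 1.0

    groups: dict[str, dict] = {}
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        try:
            dim = float(row["dim"])
            milk = float(row["milk_kg"]) * factor
            parity = normalize_parity(row["parity_group"])
            td = TestDay(dim=dim, milk=milk)
        except (TypeError, ValueError) as exc:
            logger.warning("%s line %d: skipping malformed row (%s)", path, line, exc)
            continue
        lid = str(row["lactation_id"])
        rec = groups.setdefault(
            lid, {"herd_id": str(row["herd_id"]), "parity": parity, "tests": {}}
        )
        if dim in rec["tests"]:
            if keep_first_duplicate:
                logger.warning(
                    "%s line %d: duplicate (lactation %s, dim %g); keeping first",
                    path, line, lid, dim,
                )
                continue
            raise FormatError(
                f"{path} line {line}: duplicate test day (lactation {lid}, dim {dim})"
            )
        rec["tests"][dim] = td

    lactations = []
    for lid, rec in groups.items():
        tests = tuple(rec["tests"][d] for d in sorted(rec["tests"]))
        lactations.append(
            Lactation(
                lactation_id=lid,
                herd_id=rec["herd_id"],
                parity_group=rec["parity"],
                tests=tests,
            )
        )
    return lactations


def write_testday_csv(path, lactations) -> None:
    """Write lactations in the test-day CSV dialect (kg, 10 sig. digits)."""
    rows = [
        {
            "lactation_id": l.lactation_id,
            "herd_id": l.herd_id,
            "parity_group": l.parity_group,
            "dim": td.dim,
            "milk_kg": td.milk,
        }
        for l in lactations
        for td in l.tests
    ]
    pd.DataFrame(rows, columns=TESTDAY_COLUMNS).to_csv(
        path, index=False, float_format="%.10g"
    )


def write_params_csv(path, fits) -> None:
    """Write FitResults (params, RMSE and derived metrics), 10 sig. digits."""
    rows = []
    for fr in fits:
        p = fr.params
        try:
            tp, yp, per = model.peak_day(p), model.peak_milk(p), model.persistence(p)
        except ValueError:
            tp = yp = per = float("nan")
        rows.append(
            {
                "lactation_id": fr.lactation_id,
                "herd_id": fr.herd_id,
                "parity_group": fr.parity_group,
                "scale": p.scale,
                "ramp": p.ramp,
                "offset": p.offset,
                "decay": p.decay,
                "rmse": fr.rmse,
                "n_tests": fr.n_tests,
                "m305": model.m305(p),
                "peak_day": tp,
                "peak_milk": yp,
                "persistence": per,
                "flags": ";".join(fr.diagnostics),
            }
        )
    pd.DataFrame(rows, columns=PARAMS_COLUMNS).to_csv(
        path, index=False, float_format="%.10g"
    )


def read_params_csv(path) -> pd.DataFrame:
    """Read a parameter file back into a DataFrame (flags as strings)."""
    df = pd.read_csv(path)
    missing = [c for c in PARAMS_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {', '.join(missing)}")
    df["flags"] = df["flags"].fillna("")
    df["parity_group"] = df["parity_group"].map(normalize_parity)
    return df


def params_from_row(row) -> MilkBotParams:
    """MilkBotParams from one parameter-file row."""
    return MilkBotParams(
        scale=float(row["scale"]),
        ramp=float(row["ramp"]),
        offset=float(row["offset"]),
        decay=float(row["decay"]),
    )


def write_truth_csv(path, cohort) -> None:
    """Write a synthetic cohort's generating-truth table."""
    cohort.truth.to_csv(path, index=False, float_format="%.10g")


def write_manifest(path, *, command: str, argv, seed=None, config=None, inputs=()):
    """Write a reproducibility manifest (inputs, config hash, seed, versions)."""
    def _hash(p):
        h = hashlib.sha256()
        with open(p, "rb") as fh:
            for chunk in iter(lambda: fh.read(65536), b""):
                h.update(chunk)
        return h.hexdigest()

    manifest = {
        "command": command,
        "argv": list(argv),
        "seed": seed,
        "config": config,
        "inputs": {str(p): _hash(p) for p in inputs if Path(p).is_file()},
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
        fh.write("\n")
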