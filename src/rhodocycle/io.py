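"""Plain-text serialization for traces and results.

Formats are deliberately simple: long-format CSV for matrices, two-column
CSV plus a JSON sidecar for assay traces, JSON for fitted results.  Floats
are written at 9 significant digits so regenerated files are byte-identical
under a fixed seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .pump import PumpTrace
from .reconstitution import RegenerationTrace

FLOAT_FMT = "%.9g"


def write_pump_trace(trace: PumpTrace, csv_path) -> None:
    csv_path = Path(csv_path)
    pd.DataFrame({"time_s": trace.times, "pH": trace.ph}).to_csv(
        csv_path, index=False, float_format=FLOAT_FMT
    )
    sidecar = {
        "light_on_s": trace.light_window[0],
        "light_off_s": trace.light_window[1],
        "cccp": trace.cccp,
        "label": trace.label,
    }
    csv_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_pump_trace(csv_path) -> PumpTrace:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    sidecar = json.loads(csv_path.with_suffix(".json").read_text())
    return PumpTrace(
        times=df["time_s"].to_numpy(),
        ph=df["pH"].to_numpy(),
        light_window=(sidecar["light_on_s"], sidecar["light_off_s"]),
        cccp=bool(sidecar.get("cccp", False)),
        label=sidecar.get("label", ""),
    )


def write_regeneration_trace(trace: RegenerationTrace, csv_path) -> None:
    cols = {"time_s": trace.times, "A_lambdamax": trace.a_lambda_max}
    if trace.a_470 is not None:
        cols["A_470"] = trace.a_470
    pd.DataFrame(cols).to_csv(csv_path, index=False, float_format=FLOAT_FMT)
    Path(csv_path).with_suffix(".json").write_text(
        json.dumps({"lambda_max_nm": trace.lambda_max, "label": trace.label},
                   indent=2)
    )


def read_regeneration_trace(csv_path) -> RegenerationTrace:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    meta = {}
    sidecar = csv_path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return RegenerationTrace(
        times=df["time_s"].to_numpy(),
        a_lambda_max=df["A_lambdamax"].to_numpy(),
        a_470=df["A_470"].to_numpy() if "A_470" in df else None,
        lambda_max=float(meta.get("lambda_max_nm", 550.0)),
        label=meta.get("label", ""),
    )


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, np.bool_):
            return bool(obj)
        return super().default(obj)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, cls=_NumpyEncoder) + "\n")
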