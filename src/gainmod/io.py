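"""Reading and writing the package's on-disk artifacts.

Trial tables travel as plain CSV with the fixed column schema; tuning
tensors and curves as compressed NumPy archives with named arrays; fits and
QC reports as JSON.  Ingestion of raw Allen Brain Observatory sessions is
deliberately not implemented — see :func:`load_allen_session`.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .decomposition import DecompositionParams, SubunitDecomposition, SubunitDecompositionResults
from .simulate import TRIAL_COLUMNS
from .tuning import DirectionSpeedCurve, TuningTensor3D

__all__ = [
    "read_trials",
    "write_trials",
    "save_tensor",
    "load_tensor",
    "save_curves",
    "load_curves",
    "fit_to_dict",
    "fit_from_dict",
    "save_fits",
    "load_fits",
    "load_allen_session",
]


def write_trials(trials: pd.DataFrame, path) -> None:
    trials[TRIAL_COLUMNS].to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    return df[TRIAL_COLUMNS]


def save_tensor(tensor: TuningTensor3D, path) -> None:
    np.savez_compressed(
        path, means=tensor.means, counts=tensor.counts, seconds=tensor.seconds
    )


def load_tensor(path) -> TuningTensor3D:
    with np.load(path) as z:
        return TuningTensor3D(
            means=z["means"], counts=z["counts"], seconds=z["seconds"]
        )


def save_curves(curves: dict, path) -> None:
    """Save a {neuron_id: DirectionSpeedCurve} mapping to one npz archive."""
    arrays = {}
    for nid, curve in curves.items():
        values = curve.values if isinstance(curve, DirectionSpeedCurve) else curve
        arrays[f"curve_{nid}"] = np.asarray(values)
    np.savez_compressed(path, **arrays)


def load_curves(path) -> dict:
    out = {}
    with np.load(path) as z:
        for key in z.files:
            nid = key.removeprefix("curve_")
            out[nid] = DirectionSpeedCurve(values=z[key])
    return out


def fit_to_dict(fit: SubunitDecompositionResults) -> dict:
    return {
        "subunit_coeffs": fit.params.subunit_coeffs.tolist(),
        "modulators": fit.params.modulators.tolist(),
        "lambda": fit.lambda_,
        "snr_db": fit.snr_db,
        "significant_subunits": fit.significant_subunits,
        "curve": fit.model.curve.tolist(),
    }


def fit_from_dict(d: dict) -> SubunitDecompositionResults:
    model = SubunitDecomposition(np.asarray(d["curve"], dtype=float))
    params = DecompositionParams(
        subunit_coeffs=np.asarray(d["subunit_coeffs"], dtype=float),
        modulators=np.asarray(d["modulators"], dtype=float),
    )
    return SubunitDecompositionResults(model, params, float(d["lambda"]), float(d["snr_db"]))


def save_fits(fits: dict, path) -> None:
    payload = {str(nid): fit_to_dict(f) for nid, f in fits.items()}
    Path(path).write_text(json.dumps(payload))


def load_fits(path) -> dict:
    payload = json.loads(Path(path).read_text())
    return {nid: fit_from_dict(d) for nid, d in payload.items()}


def load_allen_session(*args, **kwargs):
    """Adapter for Allen Brain Observatory sessions — not implemented.

    This package consumes trial-level tables (see
    :data:`gainmod.simulate.TRIAL_COLUMNS`).  To analyze Allen Brain
    Observatory recordings, extract per-frame dF/F, stimulus direction,
    temporal frequency and running speed with the AllenSDK, assemble them
    into that long format (one row per imaging frame, ``duration_s`` = the
    frame period) and feed the result to :func:`gainmod.tuning.build_tensor`
    via :func:`read_trials`.
    """
    raise NotImplementedError(
        "Allen Brain Observatory ingestion is out of scope; assemble a "
        "trial-level CSV with columns "
        f"{TRIAL_COLUMNS} using the AllenSDK and use read_trials() instead."
    )
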