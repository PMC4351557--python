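"""Plain-text formats for series, spectra and analysis tables.

All series travel as columnar text (one header line of site ids, one row
per frame); spectra as two-column text (frequency Hz, power) preceded by a
single ``#``-prefixed JSON provenance header; parameters and seeds as
sidecar JSON.  Large ensembles can be stored as .npz array containers.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .dichotomize import CountSeries, DichotomousSeries
from .spectral import PS_INV_TO_HZ, PowerSpectrum


def write_series(path: str | Path, series_list) -> None:
    """Write series as columns: header of site ids, one row per frame."""
    cols = {}
    for i, s in enumerate(series_list):
        name = getattr(s, "site_id", "") or f"site{i}"
        cols[name] = np.asarray(getattr(s, "values", getattr(s, "states", s)))
    df = pd.DataFrame(cols)
    df.to_csv(path, sep="\t", index=False)


def read_count_series(path: str | Path, dt: float = 1.0) -> list[CountSeries]:
    df = pd.read_csv(path, sep="\t")
    return [CountSeries(df[c].to_numpy(), dt=dt, site_id=str(c)) for c in df.columns]


def read_dichotomous_series(path: str | Path, dt: float = 1.0) -> list[DichotomousSeries]:
    df = pd.read_csv(path, sep="\t")
    return [DichotomousSeries(df[c].to_numpy(), dt=dt, site_id=str(c)) for c in df.columns]


def write_ensemble_npz(path: str | Path, states: np.ndarray, **meta) -> None:
    """Binary array container for large ensembles, with metadata echoed."""
    np.savez_compressed(path, states=states, meta=json.dumps(meta, sort_keys=True))


def read_ensemble_npz(path: str | Path) -> tuple[np.ndarray, dict]:
    with np.load(path, allow_pickle=False) as z:
        return z["states"], json.loads(str(z["meta"]))


def write_spectrum(path: str | Path, spectrum: PowerSpectrum, **provenance) -> None:
    """Two-column text (frequency Hz, power) with a JSON provenance header."""
    header = {
        "n_ensemble": spectrum.n_ensemble,
        "measurement_time_ps": spectrum.measurement_time,
        **provenance,
    }
    with open(path, "w") as fh:
        fh.write("# " + json.dumps(header, sort_keys=True) + "\n")
        for f, p in zip(spectrum.freqs_hz, spectrum.power):
            fh.write(f"{f:.10e}\t{p:.10e}\n")


def read_spectrum(path: str | Path) -> tuple[PowerSpectrum, dict]:
    with open(path) as fh:
        first = fh.readline()
        header = json.loads(first.lstrip("# ")) if first.startswith("#") else {}
        data = np.loadtxt(fh)
    sp = PowerSpectrum(
        data[:, 0] / PS_INV_TO_HZ,
        data[:, 1],
        n_ensemble=int(header.get("n_ensemble", 1)),
        measurement_time=float(header.get("measurement_time_ps", float("nan"))),
    )
    return sp, header


def write_sidecar(path: str | Path, **params) -> None:
    Path(path).write_text(json.dumps(params, sort_keys=True, indent=2) + "\n")


def write_table(path: str | Path, df: pd.DataFrame, **provenance) -> None:
    """Tab-separated table with a JSON provenance header line."""
    with open(path, "w") as fh:
        fh.write("# " + json.dumps(provenance, sort_keys=True) + "\n")
        df.to_csv(fh, sep="\t", index=False)
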