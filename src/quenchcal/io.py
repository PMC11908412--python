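"""CSV readers/writers for spectra, decays and correlation curves, plus
key-value report files.

All tabular formats are comma-separated UTF-8 with a required header row;
column names are matched case-insensitively against a synonym table so the
readers tolerate the naming variations of deposited data.  Axis columns
(wavelength, time, lag) must be strictly increasing and every cell numeric —
violations raise distinct, messageful errors.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .fcs import CorrelationCurve
from .spectra import Spectrum
from .tcspc import DecayHistogram, InstrumentResponse

__all__ = [
    "TableFormatError",
    "read_table",
    "read_spectrum",
    "write_spectrum",
    "read_decay",
    "write_decay",
    "read_irf",
    "read_correlation",
    "write_correlation",
    "read_distance_table",
    "write_distance_table",
    "write_report",
    "read_report",
    "file_checksum",
]


class TableFormatError(ValueError):
    """A CSV file does not match the expected schema."""


# canonical column -> accepted synonyms (lower-case, stripped)
_SYNONYMS: Mapping[str, tuple[str, ...]] = {
    "wavelength_nm": ("wavelength_nm", "wavelength", "lambda_nm", "lambda", "wl_nm", "nm"),
    "value": ("value", "absorbance", "abs", "fluorescence", "intensity",
              "signal", "counts", "emission", "excitation", "a.u.", "au"),
    "time_ps": ("time_ps", "time", "t_ps", "channel_time_ps", "ps"),
    "counts": ("counts", "photons", "count", "events"),
    "lag_s": ("lag_s", "lag", "tau_s", "tau", "lagtime_s", "lag_time_s"),
    "g": ("g", "g_tau", "correlation", "autocorrelation", "g(tau)"),
    "stderr": ("stderr", "std_err", "sd", "sigma", "error", "se"),
    "distance_a": ("distance_a", "distance", "d_a", "separation_a", "r_mp_a", "r_a"),
    "emission": ("emission", "fluorescence", "f", "signal", "intensity", "value"),
    "time_s": ("time_s", "t_s", "time"),
}


def read_table(path, columns: Sequence[str],
               monotone: Sequence[str] = ()) -> dict[str, np.ndarray]:
    """Read named columns from a headered CSV.

    ``columns`` are canonical names resolved case-insensitively through the
    synonym table; optional columns may be suffixed ``"?"``.  Columns listed
    in ``monotone`` must be strictly increasing.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - wrap any parse failure
        raise TableFormatError(f"{path}: cannot parse CSV ({exc})") from exc
    available = {str(c).strip().lower(): c for c in frame.columns}

    out: dict[str, np.ndarray] = {}
    used: set[str] = set()
    for spec in columns:
        optional = spec.endswith("?")
        name = spec.rstrip("?")
        found = None
        for syn in _SYNONYMS.get(name, (name,)):
            if syn in available and available[syn] not in used:
                found = available[syn]
                break
        if found is None:
            if optional:
                continue
            raise TableFormatError(
                f"{path}: missing required column {name!r} "
                f"(accepted names: {', '.join(_SYNONYMS.get(name, (name,)))})")
        used.add(found)
        col = pd.to_numeric(frame[found], errors="coerce").to_numpy(dtype=float)
        if np.any(np.isnan(col)):
            bad = int(np.flatnonzero(np.isnan(col))[0])
            raise TableFormatError(
                f"{path}: non-numeric cell in column {found!r} at data row {bad}")
        out[name] = col

    for name in monotone:
        if name in out and np.any(np.diff(out[name]) <= 0):
            raise TableFormatError(
                f"{path}: column {name!r} must be strictly increasing")
    return out


def read_spectrum(path, kind: str = "absorption") -> Spectrum:
    cols = read_table(path, ["wavelength_nm", "value"], monotone=["wavelength_nm"])
    return Spectrum(cols["wavelength_nm"], cols["value"], kind)


def write_spectrum(spectrum: Spectrum, path) -> None:
    pd.DataFrame({"wavelength_nm": spectrum.wavelengths,
                  "value": spectrum.values}).to_csv(path, index=False)


def read_decay(path, label: str = "") -> DecayHistogram:
    cols = read_table(path, ["time_ps", "counts"], monotone=["time_ps"])
    widths = np.diff(cols["time_ps"])
    if not np.allclose(widths, widths[0], rtol=1e-6):
        raise TableFormatError(f"{path}: decay channel axis must be uniform")
    return DecayHistogram(channel_width_ps=float(widths[0]),
                          counts=cols["counts"], label=label or Path(path).stem)


def write_decay(hist: DecayHistogram, path) -> None:
    t = (np.arange(hist.n_channels) + 0.5) * hist.channel_width_ps
    pd.DataFrame({"time_ps": t, "counts": hist.counts}).to_csv(path, index=False)


def read_irf(path) -> InstrumentResponse:
    cols = read_table(path, ["time_ps", "counts"], monotone=["time_ps"])
    widths = np.diff(cols["time_ps"])
    if not np.allclose(widths, widths[0], rtol=1e-6):
        raise TableFormatError(f"{path}: IRF channel axis must be uniform")
    return InstrumentResponse(channel_width_ps=float(widths[0]),
                              values=cols["counts"])


def read_correlation(path, power_label: str = "") -> CorrelationCurve:
    cols = read_table(path, ["lag_s", "g", "stderr?"], monotone=["lag_s"])
    return CorrelationCurve(cols["lag_s"], cols["g"], cols.get("stderr"),
                            power_label=power_label)


def write_correlation(curve: CorrelationCurve, path) -> None:
    data = {"lag_s": curve.lags_s, "g": curve.g}
    if curve.stderr is not None:
        data["stderr"] = curve.stderr
    pd.DataFrame(data).to_csv(path, index=False)


def read_distance_table(path) -> list[tuple[float, float]]:
    cols = read_table(path, ["distance_a", "emission"])
    return list(zip(cols["distance_a"].tolist(), cols["emission"].tolist()))


def write_distance_table(points: Sequence[tuple[float, float]], path) -> None:
    pd.DataFrame({"distance_a": [p[0] for p in points],
                  "emission": [p[1] for p in points]}).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Key-value reports
# ---------------------------------------------------------------------------

def _flatten(prefix: str, obj, out: dict) -> None:
    if isinstance(obj, Mapping):
        for k, v in obj.items():
            _flatten(f"{prefix}.{k}" if prefix else str(k), v, out)
    elif isinstance(obj, (list, tuple, np.ndarray)):
        arr = np.asarray(obj)
        if arr.ndim == 0:
            out[prefix] = arr.item()
        else:
            for i, v in enumerate(arr.tolist()):
                _flatten(f"{prefix}[{i}]", v, out)
    else:
        out[prefix] = obj


def write_report(result: Mapping, path) -> None:
    """Write a nested mapping as a flat ``key = value`` text report.

    Nested keys are dotted, sequence entries indexed; values are repr'd in
    full precision so the report round-trips losslessly through
    :func:`read_report`."""
    flat: dict = {}
    _flatten("", result, flat)
    lines = []
    for key, value in flat.items():
        if isinstance(value, float):
            lines.append(f"{key} = {value!r}")
        else:
            lines.append(f"{key} = {value}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_report(path) -> dict:
    """Parse a ``key = value`` report back into a flat dict (numbers are
    converted where possible)."""
    out: dict = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#") or "=" not in line:
            continue
        key, _, raw = line.partition("=")
        raw = raw.strip()
        value: object = raw
        for conv in (int, float):
            try:
                value = conv(raw)
                break
            except ValueError:
                continue
        if raw in ("True", "False"):
            value = raw == "True"
        out[key.strip()] = value
    return out


def file_checksum(path) -> str:
    """SHA-256 of a file, used to log which inputs produced a report."""
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
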