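"""Series/curve/report I/O and the deterministic test fixture set.

Series files are single-column UTF-8 text, one value per line, with
optional ``# key=value`` header comments carrying generator parameters.
CSV files with a ``value`` column are also accepted.  Entropy curves are
two-column ``l S`` text; analysis reports are flat ``key=value`` text
that round-trips losslessly.
"""

from __future__ import annotations

import csv
import io as _stdio
from pathlib import Path

import numpy as np

from .dea import EntropyCurve
from .generators import (FbmParams, FluctuationSeries, RenewalParams,
                         combined_series, fill_laminar_coin_toss,
                         generate_event_train, generate_fgn)

__all__ = [
    "write_series",
    "read_series",
    "write_curve",
    "read_curve",
    "format_report",
    "parse_report",
    "write_report",
    "make_fixtures",
]


def _coerce(text: str):
    """Best-effort str -> int/float/str for header and report values."""
    for cast in (int, float):
        try:
            return cast(text)
        except ValueError:
            continue
    return text


def write_series(path, series: FluctuationSeries,
                 params: dict | None = None) -> None:
    """Write one value per line with ``# key=value`` header comments."""
    path = Path(path)
    header = dict(series.params)
    if params:
        header.update(params)
    with path.open("w", encoding="utf-8") as fh:
        for key, val in header.items():
            fh.write(f"# {key}={val}\n")
        np.savetxt(fh, series.values, fmt="%.17g")


def read_series(path) -> FluctuationSeries:
    """Read a series file (plain text or CSV with a ``value`` column)."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if not text.strip():
        raise ValueError(f"empty series file: {path}")
    header: dict = {}
    body_lines = []
    for line in text.splitlines():
        stripped = line.strip()
        if stripped.startswith("#"):
            payload = stripped.lstrip("#").strip()
            if "=" in payload:
                key, _, val = payload.partition("=")
                header[key.strip()] = _coerce(val.strip())
            continue
        if stripped:
            body_lines.append(stripped)
    if not body_lines:
        raise ValueError(f"series file has a header but no data: {path}")
    if "," in body_lines[0]:
        reader = csv.DictReader(_stdio.StringIO("\n".join(body_lines)))
        if reader.fieldnames is None or "value" not in reader.fieldnames:
            raise ValueError(f"CSV series file needs a 'value' column: {path}")
        values = np.array([float(row["value"]) for row in reader])
    else:
        values = np.array([float(tok) for tok in body_lines])
    return FluctuationSeries(values=values, params=header)


def write_curve(path, curve: EntropyCurve) -> None:
    """Two-column ``l S`` text, ready for replotting."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"# bin_width={curve.bin_width}\n")
        for l, S in zip(curve.ls, curve.Ss):
            fh.write(f"{int(l)} {S:.10g}\n")


def read_curve(path) -> EntropyCurve:
    bin_width = 1.0
    ls, Ss = [], []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("#"):
            payload = stripped.lstrip("#").strip()
            if payload.startswith("bin_width="):
                bin_width = float(payload.split("=", 1)[1])
            continue
        l_tok, s_tok = stripped.split()
        ls.append(int(l_tok))
        Ss.append(float(s_tok))
    return EntropyCurve(ls=np.array(ls), Ss=np.array(Ss), bin_width=bin_width)


def format_report(report: dict) -> str:
    """Flat ``key=value`` lines; insertion order preserved."""
    return "".join(f"{key}={val}\n" for key, val in report.items())


def parse_report(text: str) -> dict:
    out: dict = {}
    for line in text.splitlines():
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        key, _, val = stripped.partition("=")
        out[key.strip()] = _coerce(val.strip())
    return out


def write_report(path, report: dict) -> None:
    Path(path).write_text(format_report(report), encoding="utf-8")


def make_fixtures(seed: int = 0) -> dict:
    """Small deterministic series for the unit-test suite.

    Everything is generated in memory from the given seed — the set
    regenerates identically across runs, so the full suite runs offline.
    """
    train_1e4 = generate_event_train(
        RenewalParams(mu=2.5, T=1.0, length=10_000, seed=seed))
    train_mu18 = generate_event_train(
        RenewalParams(mu=1.8, T=1.0, length=10_000, seed=seed + 1))
    fixtures = {
        "train_mu2.5_1e4": train_1e4,
        "train_mu1.8_1e4": train_mu18,
        "crucial_mu2.5_1e4": fill_laminar_coin_toss(train_1e4, W=1.0,
                                                    seed=seed + 2),
        "crucial_mu1.8_1e4": fill_laminar_coin_toss(train_mu18, W=1.0,
                                                    seed=seed + 3),
        "fgn_h0.6_4096": generate_fgn(FbmParams(H=0.6, length=4096,
                                                seed=seed + 4)),
        "fgn_h0.9_4096": generate_fgn(FbmParams(H=0.9, length=4096,
                                                seed=seed + 5)),
        "combined_h0.9_mu2.5_1e4": combined_series(mu=2.5, H=0.9, T=1.0,
                                                   length=10_000,
                                                   seed=seed + 6),
    }
    return fixtures
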