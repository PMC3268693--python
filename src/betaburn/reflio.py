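"""File formats: columnar reflection files, XDS_ASCII subset, tables, protocols.

The native reflection format is a tab-separated text file with a commented
header (format version, wedge index, nominal dose, d_min) and one row per
reflection: id, s^2 (A^-2), J, sigma_J.  Numbers are serialized with enough
digits for a lossless round trip.  A read-only subset of XDS_ASCII (.HKL)
files is supported for real integrated data: h k l, Iobs, sigma(Iobs) plus
the unit-cell line, from which s^2 is computed via the general triclinic
metric (gemmi.UnitCell).
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import gemmi

from .betafit import DecayResult, SensitivityReport, round_report
from .exceptions import ReflectionParseError, XdsFormatError
from .protocol import BurnCycle, CollectionCycle, Protocol
from .scaling import WedgeScale
from .sim import WedgeDataset

__all__ = [
    "write_reflections",
    "read_reflections",
    "read_xds_ascii",
    "write_protocol",
    "read_protocol",
    "write_scale_table",
    "read_scale_table",
    "write_report",
]

FORMAT_VERSION = 1


def write_reflections(dataset: WedgeDataset, path: str | Path) -> None:
    """Write a wedge to the native columnar TSV format."""
    path = Path(path)
    d_min = "None" if dataset.d_min is None else f"{float(dataset.d_min):.17g}"
    lines = [
        f"# betaburn-reflections format_version={FORMAT_VERSION}",
        f"# wedge_index={dataset.wedge_index}",
        f"# nominal_dose_mgy={float(dataset.nominal_dose):.17g}",
        f"# d_min_a={d_min}",
        "id\ts2\tJ\tsigma_J",
    ]
    for i in range(len(dataset)):
        lines.append(
            f"{dataset.ids[i]}\t{dataset.s2[i]:.17g}\t{dataset.J[i]:.17g}\t{dataset.sigma_J[i]:.17g}"
        )
    path.write_text("\n".join(lines) + "\n")


def read_reflections(path: str | Path) -> WedgeDataset:
    """Read a wedge from the native format; lossless inverse of write_reflections."""
    path = Path(path)
    header: dict[str, str] = {}
    ids: list[int] = []
    s2: list[float] = []
    J: list[float] = []
    sig: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                for token in line[1:].split():
                    if "=" in token:
                        key, _, val = token.partition("=")
                        header[key] = val
                continue
            if line.startswith("id\t"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ReflectionParseError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
            try:
                ids.append(int(parts[0]))
                s2.append(float(parts[1]))
                J.append(float(parts[2]))
                sig.append(float(parts[3]))
            except ValueError as exc:
                raise ReflectionParseError(f"{path}:{lineno}: {exc}") from exc
            if math.isnan(sig[-1]):
                raise ReflectionParseError(f"{path}:{lineno}: NaN sigma_J")
    if "format_version" not in header:
        raise ReflectionParseError(f"{path}: missing format header")
    d_min_raw = header.get("d_min_a", "None")
    return WedgeDataset(
        wedge_index=int(header.get("wedge_index", 0)),
        nominal_dose=float(header.get("nominal_dose_mgy", 0.0)),
        ids=np.array(ids, dtype=np.int64),
        s2=np.array(s2),
        J=np.array(J),
        sigma_J=np.array(sig),
        d_min=None if d_min_raw == "None" else float(d_min_raw),
    )


def read_xds_ascii(
    path: str | Path, nominal_dose: float = 0.0, wedge_index: int = 0
) -> WedgeDataset:
    """Read the minimal XDS_ASCII subset: H, K, L, IOBS, SIGMA(IOBS).

    Requires a !FORMAT=XDS_ASCII header with ITEM_H/K/L, ITEM_IOBS,
    ITEM_SIGMA(IOBS) column declarations and a !UNIT_CELL_CONSTANTS line;
    s^2 = 1/(4 d^2) is computed from the cell with the general triclinic
    formula.  The nominal dose is supplied by the caller (the file does not
    carry it).
    """
    path = Path(path)
    cols: dict[str, int] = {}
    cell: gemmi.UnitCell | None = None
    rows: list[tuple[int, int, int, float, float]] = []
    in_header = True
    with open(path) as fh:
        first = fh.readline()
        if "FORMAT=XDS_ASCII" not in first:
            raise XdsFormatError(f"{path}: missing !FORMAT=XDS_ASCII header")
        for lineno, raw in enumerate(fh, start=2):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("!"):
                if line.startswith("!UNIT_CELL_CONSTANTS="):
                    vals = [float(v) for v in line.split("=", 1)[1].split()]
                    if len(vals) != 6:
                        raise XdsFormatError(f"{path}:{lineno}: bad unit-cell line")
                    cell = gemmi.UnitCell(*vals)
                for item in ("ITEM_H", "ITEM_K", "ITEM_L", "ITEM_IOBS", "ITEM_SIGMA(IOBS)"):
                    if line.startswith(f"!{item}="):
                        cols[item] = int(line.split("=", 1)[1]) - 1
                if line.startswith("!END_OF_HEADER"):
                    in_header = False
                if line.startswith("!END_OF_DATA"):
                    break
                continue
            if in_header:
                continue
            parts = line.split()
            try:
                rows.append(
                    (
                        int(parts[cols["ITEM_H"]]),
                        int(parts[cols["ITEM_K"]]),
                        int(parts[cols["ITEM_L"]]),
                        float(parts[cols["ITEM_IOBS"]]),
                        float(parts[cols["ITEM_SIGMA(IOBS)"]]),
                    )
                )
            except (KeyError, IndexError, ValueError) as exc:
                raise XdsFormatError(f"{path}:{lineno}: {exc}") from exc
    missing = {"ITEM_H", "ITEM_K", "ITEM_L", "ITEM_IOBS", "ITEM_SIGMA(IOBS)"} - set(cols)
    if missing:
        raise XdsFormatError(f"{path}: missing column declaration(s): {sorted(missing)}")
    if cell is None:
        raise XdsFormatError(f"{path}: missing !UNIT_CELL_CONSTANTS")
    s2 = np.array([cell.calculate_1_d2([h, k, l]) / 4.0 for h, k, l, *_ in rows])
    return WedgeDataset(
        wedge_index=wedge_index,
        nominal_dose=nominal_dose,
        ids=np.arange(len(rows), dtype=np.int64),
        s2=s2,
        J=np.array([r[3] for r in rows]),
        sigma_J=np.array([r[4] for r in rows]),
    )


# --- protocol serialization -------------------------------------------------


def write_protocol(protocol: Protocol, path: str | Path) -> None:
    """Serialize a protocol to JSON: one record per cycle plus metadata."""
    records = []
    for c in protocol.cycles:
        rec = {
            "type": c.kind,
            "start_angle": c.start_angle,
            "total_rotation": c.total_rotation,
            "transmission": c.transmission,
            "planned_dose_mgy": c.planned_dose,
        }
        if isinstance(c, CollectionCycle):
            rec.update(
                frame_width=c.frame_width,
                exposure_per_frame_s=c.exposure_per_frame,
                d_min_a=c.d_min,
            )
        else:
            rec.update(exposure_s=c.exposure)
        records.append(rec)
    payload = {
        "assumed_beta": protocol.assumed_beta,
        "d_min_a": protocol.d_min,
        "dose_rate_mgy_s": protocol.dose_rate,
        "cycles": records,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_protocol(path: str | Path) -> Protocol:
    payload = json.loads(Path(path).read_text())
    cycles: list[CollectionCycle | BurnCycle] = []
    for rec in payload["cycles"]:
        if rec["type"] == "collect":
            cycles.append(
                CollectionCycle(
                    kind="collect",
                    start_angle=rec["start_angle"],
                    total_rotation=rec["total_rotation"],
                    frame_width=rec["frame_width"],
                    exposure_per_frame=rec["exposure_per_frame_s"],
                    transmission=rec["transmission"],
                    d_min=rec["d_min_a"],
                    planned_dose=rec["planned_dose_mgy"],
                )
            )
        else:
            cycles.append(
                BurnCycle(
                    kind="burn",
                    start_angle=rec["start_angle"],
                    total_rotation=rec["total_rotation"],
                    exposure=rec["exposure_s"],
                    transmission=rec["transmission"],
                    planned_dose=rec["planned_dose_mgy"],
                )
            )
    return Protocol(
        cycles=tuple(cycles),
        assumed_beta=payload["assumed_beta"],
        d_min=payload["d_min_a"],
        dose_rate=payload["dose_rate_mgy_s"],
    )


# --- tables -----------------------------------------------------------------


def write_scale_table(
    scales: Sequence[WedgeScale], path: str | Path, snr_last: Sequence[float] | None = None
) -> None:
    """Per-wedge scale table as TSV: index, dose, k, B, se_B, last-shell SNR."""
    df = pd.DataFrame(
        {
            "wedge_index": [s.wedge_index for s in scales],
            "nominal_dose": [f"{s.nominal_dose:.17g}" for s in scales],
            "k": [f"{s.k:.17g}" for s in scales],
            "B": [f"{s.B:.17g}" for s in scales],
            "se_B": [f"{s.se_B:.17g}" for s in scales],
            "snr_last": [
                f"{float(v):.17g}"
                for v in (snr_last if snr_last is not None else [math.nan] * len(scales))
            ],
        }
    )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_scale_table(path: str | Path) -> list[WedgeScale]:
    df = pd.read_csv(path, sep="\t")
    return [
        WedgeScale(
            wedge_index=int(r.wedge_index),
            k=float(r.k),
            B=float(r.B),
            se_B=float(r.se_B),
            nominal_dose=float(r.nominal_dose),
        )
        for r in df.itertuples()
    ]


def write_report(
    entries: Sequence[tuple[str, SensitivityReport]], path: str | Path
) -> pd.DataFrame:
    """Sensitivity report TSV: one row per crystal position, 2-decimal betas.

    Columns mirror a per-sample summary table: crystal, position, beta,
    beta_average, beta_std (blank rows after the first position; NA for
    single-position samples), beta_corrected.
    """
    rows = []
    for crystal, rep in entries:
        for i, b in enumerate(rep.per_position_betas):
            rows.append(
                {
                    "crystal": crystal,
                    "position": i + 1,
                    "beta": f"{round_report(b):.2f}",
                    "beta_average": f"{round_report(rep.beta_average):.2f}" if i == 0 else "",
                    "beta_std": (
                        ("NA" if rep.std_is_na else f"{round_report(rep.beta_std):.2f}")
                        if i == 0
                        else ""
                    ),
                    "beta_corrected": f"{round_report(rep.beta_corrected[i]):.2f}",
                }
            )
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")
    return df
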