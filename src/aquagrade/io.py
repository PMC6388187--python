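"""Reading and writing well panels as CSV.

Dialect: comma-separated, UTF-8, ``.`` decimal, mandatory header of
``well_id`` followed by registered indicator codes.  Units are fixed by the
indicator registry, never per-file.  Lines starting with ``#`` are metadata
comments (the generator writes its seed there) and are skipped on read.
"""

from __future__ import annotations

import math

import pandas as pd

from .errors import InputDataError
from .samples import WellSample
from .standards import INDICATOR_UNITS


def read_wells_csv(path) -> list[WellSample]:
    """Parse a wells CSV into samples; blank cells become missing values."""
    try:
        frame = pd.read_csv(path, comment="#", dtype=str)
    except FileNotFoundError:
        raise InputDataError(f"input file not found: {path}") from None
    except Exception as exc:  # malformed CSV
        raise InputDataError(f"cannot parse {path}: {exc}") from exc
    if "well_id" not in frame.columns:
        raise InputDataError(f"{path}: header must contain a 'well_id' column")
    unknown = [c for c in frame.columns if c != "well_id" and c not in INDICATOR_UNITS]
    if unknown:
        raise InputDataError(
            f"{path}: unknown indicator column(s) {unknown}; "
            f"recognized codes: {sorted(INDICATOR_UNITS)}"
        )
    ids = frame["well_id"].tolist()
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise InputDataError(f"{path}: duplicate well_id(s) {sorted(dupes)}")
    samples = []
    for row_no, (_, row) in enumerate(frame.iterrows(), start=2):
        values = {}
        for code in frame.columns:
            if code == "well_id":
                continue
            cell = row[code]
            if cell is None or (isinstance(cell, float) and math.isnan(cell)) \
                    or str(cell).strip() == "":
                continue
            try:
                value = float(cell)
            except ValueError:
                raise InputDataError(
                    f"{path}: non-numeric value {cell!r} at row {row_no}, "
                    f"column {code!r}"
                ) from None
            if code != "pH" and value < 0:
                raise InputDataError(
                    f"{path}: negative concentration {value} at row {row_no}, "
                    f"column {code!r}"
                )
            values[code] = value
        samples.append(WellSample(well_id=str(row["well_id"]), values=values))
    return samples


def write_wells_csv(samples: list[WellSample], path, seed: int | None = None) -> None:
    """Write a panel; column order follows the indicator registry."""
    codes = [c for c in INDICATOR_UNITS if any(c in s for s in samples)]
    frame = pd.DataFrame(
        [{"well_id": s.well_id, **{c: s.values.get(c) for c in codes}} for s in samples]
    )
    with open(path, "w", encoding="utf-8") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        units = ",".join(f"{c}[{INDICATOR_UNITS[c]}]" for c in codes)
        fh.write(f"# columns: well_id,{units}\n")
        frame.to_csv(fh, index=False)
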