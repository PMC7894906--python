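"""CSV and JSON input/output shared by the CLI.

Long-format input CSV: header ``subject,index,value`` (optional ``group``),
UTF-8, "." decimal separator.  Band output CSV: header
``subject,index,value,lower,upper,atypical,method`` with 6-decimal fixed
formatting.
"""

from __future__ import annotations

import csv
import json
import math
from pathlib import Path

import numpy as np

from .data_model import ObservationTable, ReferenceBand, validate_table
from .em import EMState
from .errors import DataError

__all__ = ["read_long_csv", "write_band", "write_draws", "state_to_json", "state_from_json"]

REQUIRED_COLUMNS = ("subject", "index", "value")


def read_long_csv(path: str | Path, log_transform: bool = False) -> ObservationTable:
    """Read and validate a long-format observation CSV.

    With ``log_transform`` the values are natural-log transformed on read
    (non-positive values are rejected).  Row order is preserved within
    subjects via the index column; an optional ``group`` column populates
    ``table.groups``.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in REQUIRED_COLUMNS if c not in header]
        if missing:
            raise DataError(f"bad header: missing columns {missing} in {path}")
        has_group = "group" in header
        records = []
        groups: dict[str, str] = {}
        for lineno, row in enumerate(reader, start=2):
            try:
                sid = row["subject"]
                idx = float(row["index"])
                val = float(row["value"])
            except (TypeError, ValueError) as exc:
                raise DataError(f"unparseable row at line {lineno} of {path}: {row!r}") from exc
            if log_transform:
                if not val > 0:
                    raise DataError(
                        f"log transform requires positive values; line {lineno} has {val!r}"
                    )
                val = math.log(val)
            records.append((sid, idx, val))
            if has_group:
                groups[str(sid)] = row["group"]
    return validate_table(records, groups=groups if has_group else None)


def write_band(band: ReferenceBand, path: str | Path, exp_transform: bool = False) -> None:
    """Write a reference band as CSV; optionally exponentiate limits/values."""
    path = Path(path)
    tx = math.exp if exp_transform else float
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["subject", "index", "value", "lower", "upper", "atypical", "method"])
        for e in band.entries:
            writer.writerow(
                [
                    e.subject_id,
                    e.index,
                    f"{tx(e.observed):.6f}",
                    f"{tx(e.lower):.6f}",
                    f"{tx(e.upper):.6f}",
                    "true" if e.atypical else "false",
                    e.method,
                ]
            )


def write_draws(draws, path: str | Path) -> None:
    """Export posterior draws as long CSV: parameter, subject, draw, value."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["parameter", "subject", "draw", "value"])
        for t in range(draws.n_draws):
            writer.writerow(["mu", "", t, f"{draws.mu[t]:.8g}"])
            writer.writerow(["tau2", "", t, f"{draws.tau2[t]:.8g}"])
        for k, sid in enumerate(draws.subject_ids):
            for t in range(draws.n_draws):
                writer.writerow(["mu_i", sid, t, f"{draws.mu_i[t, k]:.8g}"])
                writer.writerow(["sigma2_i", sid, t, f"{draws.sigma2_i[t, k]:.8g}"])


def state_to_json(state: EMState, path: str | Path) -> None:
    """Serialise a streaming-EM state (all fields) to JSON."""
    payload = {
        "subject_ids": state.subject_ids,
        "mu_hat": state.mu_hat,
        "tau2_hat": state.tau2_hat,
        "sigma2_hat": state.sigma2_hat.tolist(),
        "mu_i_hat": state.mu_i_hat.tolist(),
        "nu_i_hat": state.nu_i_hat.tolist(),
        "rho_i_hat": state.rho_i_hat.tolist(),
        "T1": state.T1,
        "T2": state.T2,
        "T3": state.T3.tolist(),
        "n_i": state.n_i.tolist(),
        "ybar_i": state.ybar_i.tolist(),
        "y2bar_i": state.y2bar_i.tolist(),
        "iteration": state.iteration,
        "converged": state.converged,
    }
    Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


def state_from_json(path: str | Path) -> EMState:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    try:
        state = EMState(
            subject_ids=list(payload["subject_ids"]),
            mu_hat=float(payload["mu_hat"]),
            tau2_hat=float(payload["tau2_hat"]),
            sigma2_hat=np.asarray(payload["sigma2_hat"], dtype=float),
            mu_i_hat=np.asarray(payload["mu_i_hat"], dtype=float),
            nu_i_hat=np.asarray(payload["nu_i_hat"], dtype=float),
            rho_i_hat=np.asarray(payload["rho_i_hat"], dtype=float),
            T1=float(payload["T1"]),
            T2=float(payload["T2"]),
            T3=np.asarray(payload["T3"], dtype=float),
            n_i=np.asarray(payload["n_i"], dtype=float),
            ybar_i=np.asarray(payload["ybar_i"], dtype=float),
            y2bar_i=np.asarray(payload["y2bar_i"], dtype=float),
            iteration=int(payload["iteration"]),
            converged=bool(payload["converged"]),
        )
    except KeyError as exc:
        raise DataError(f"state file {path} is missing field {exc}") from exc
    return state
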