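"""File formats: item-bank CSV/JSON, response matrices, session logs.

Bank CSV columns: ``item_id, scale_label, primary_dimension, a_1..a_D, d,
lower, upper, start_age_group`` (start_age_group blank or "4"/"5"/"6");
missing asymptotes default to 0 and 1.  The JSON mirror uses identical
field names.  Response CSV: ``respondent_id`` plus one column per item_id;
an empty cell is a missing response.  All round-trips are lossless.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cat_engine import CatSession
from .item_model import BankError, ItemBank, ItemParameters


class SchemaError(ValueError):
    """Malformed input file; message carries row/column context."""


def bank_to_frame(bank: ItemBank) -> pd.DataFrame:
    rows = []
    start_of = {iid: grp for grp, iid in bank.starting_items.items()}
    for it in bank.items:
        row = {
            "item_id": it.item_id,
            "scale_label": it.scale_label,
            "primary_dimension": it.primary_dimension,
        }
        for k in range(bank.n_dimensions):
            row[f"a_{k + 1}"] = it.loadings[k]
        row["d"] = it.intercept
        row["lower"] = it.lower_asymptote
        row["upper"] = it.upper_asymptote
        row["start_age_group"] = start_of.get(it.item_id, "")
        rows.append(row)
    return pd.DataFrame(rows)


def write_bank(bank: ItemBank, path: str | Path) -> None:
    """Write a bank as CSV (or JSON when the suffix is .json)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = {
            "n_dimensions": bank.n_dimensions,
            "dimension_labels": bank.dimension_labels,
            "trait_covariance": bank.trait_covariance.tolist(),
            "items": bank_to_frame(bank).to_dict(orient="records"),
        }
        path.write_text(json.dumps(payload, indent=1))
    else:
        frame = bank_to_frame(bank)
        header = "# trait_covariance: " + json.dumps(
            bank.trait_covariance.tolist()
        )
        labels = "# dimension_labels: " + json.dumps(bank.dimension_labels)
        path.write_text(
            header + "\n" + labels + "\n" + frame.to_csv(index=False)
        )


def _items_from_records(records, n_dim: int) -> tuple[list[ItemParameters], dict]:
    items, starting = [], {}
    for lineno, rec in enumerate(records, start=1):
        try:
            loadings = [float(rec.get(f"a_{k + 1}", 0.0) or 0.0) for k in range(n_dim)]
            lower = rec.get("lower", "")
            upper = rec.get("upper", "")
            item = ItemParameters(
                item_id=str(rec["item_id"]),
                loadings=np.array(loadings),
                intercept=float(rec["d"]),
                lower_asymptote=float(lower) if lower not in ("", None) and not pd.isna(lower) else 0.0,
                upper_asymptote=float(upper) if upper not in ("", None) and not pd.isna(upper) else 1.0,
                primary_dimension=int(rec.get("primary_dimension", 0) or 0),
                scale_label=str(rec.get("scale_label", "") or ""),
            )
        except (KeyError, ValueError, TypeError, BankError) as exc:
            raise SchemaError(f"bank row {lineno}: {exc}") from exc
        items.append(item)
        grp = rec.get("start_age_group", "")
        if grp not in ("", None) and not pd.isna(grp):
            starting[str(grp).split(".")[0]] = item.item_id
    return items, starting


def read_bank(path: str | Path) -> ItemBank:
    """Read a bank CSV/JSON written by :func:`write_bank`."""
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"bank file {path} does not exist")
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        n_dim = int(payload["n_dimensions"])
        items, starting = _items_from_records(payload["items"], n_dim)
        return ItemBank(
            items=items,
            n_dimensions=n_dim,
            dimension_labels=list(payload.get("dimension_labels", [])),
            trait_covariance=np.array(payload["trait_covariance"]),
            starting_items=starting,
        )
    text = path.read_text().splitlines()
    cov = labels = None
    body_start = 0
    for i, line in enumerate(text):
        if line.startswith("# trait_covariance:"):
            cov = np.array(json.loads(line.split(":", 1)[1]))
            body_start = i + 1
        elif line.startswith("# dimension_labels:"):
            labels = json.loads(line.split(":", 1)[1])
            body_start = i + 1
        else:
            break
    body = "\n".join(text[body_start:])
    if not body.strip():
        raise SchemaError(f"bank file {path} is empty")
    frame = pd.read_csv(
        __import__("io").StringIO(body), dtype={"item_id": str}
    )
    if "item_id" not in frame.columns or "d" not in frame.columns:
        raise SchemaError(f"bank file {path}: missing item_id or d column")
    a_cols = sorted(
        (c for c in frame.columns if c.startswith("a_")),
        key=lambda c: int(c.split("_")[1]),
    )
    if not a_cols:
        raise SchemaError(f"bank file {path}: no loading columns a_1..a_D")
    n_dim = len(a_cols)
    items, starting = _items_from_records(frame.to_dict(orient="records"), n_dim)
    return ItemBank(
        items=items,
        n_dimensions=n_dim,
        dimension_labels=list(labels) if labels else [],
        trait_covariance=cov,
        starting_items=starting,
    )


def read_responses(path: str | Path) -> pd.DataFrame:
    """Response matrix CSV -> DataFrame indexed by respondent_id.

    Cells must be 0, 1 or empty (missing); anything else raises
    :class:`SchemaError` naming the offending row and column.
    """
    frame = pd.read_csv(path, dtype={"respondent_id": str})
    if "respondent_id" not in frame.columns:
        raise SchemaError("responses file needs a respondent_id column")
    frame = frame.set_index("respondent_id")
    for col in frame.columns:
        vals = pd.to_numeric(frame[col], errors="coerce")
        bad = frame[col].notna() & vals.isna()
        if bad.any():
            row = frame.index[bad.argmax()]
            raise SchemaError(
                f"non-numeric response at row {row!r}, column {col!r}"
            )
        nonmissing = vals.dropna()
        if not nonmissing.isin((0, 1)).all():
            row = vals.index[(~vals.isin((0, 1))) & vals.notna()][0]
            raise SchemaError(
                f"response not in {{0,1}} at row {row!r}, column {col!r}"
            )
        frame[col] = vals
    return frame


def write_responses(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, index_label="respondent_id")


def write_session_log(session: CatSession, path: str | Path) -> None:
    """JSONL session log: one record per administered item."""
    labels = session.bank.dimension_labels
    with open(path, "w") as fh:
        for k, (iid, resp, est) in enumerate(
            zip(session.administered, session.responses, session.estimate_history)
        ):
            rec = {
                "position": k + 1,
                "item_id": iid,
                "response": resp,
                "theta": dict(zip(labels, map(float, est.theta))),
                "sem": dict(zip(labels, map(float, est.sem))),
                "stopped": bool(
                    session.stopped and k == len(session.administered) - 1
                ),
            }
            if rec["stopped"]:
                rec["stop_reason"] = session.stop_reason
            fh.write(json.dumps(rec) + "\n")


def read_session_log(path: str | Path) -> list[dict]:
    with open(path) as fh:
        return [json.loads(line) for line in fh if line.strip()]


def write_summary(summary, path: str | Path) -> None:
    """Simulation summary table CSV (one row per statistic)."""
    summary.summary_table().to_csv(path, index_label="statistic")
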