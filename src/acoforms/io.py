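"""Delimited-text and JSON round-trips for banks, responses, profiles, results.

All tabular artifacts are UTF-8 comma-separated text with a header row;
results and profiles are JSON.  Written artifacts embed the seed, a config
hash and the package version for provenance.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bank import ItemBank, ItemSpec, ResponseData
from .criteria import CriterionProfile

__all__ = [
    "write_calibrated_form",
    "write_curves",
    "read_item_bank",
    "write_item_bank",
    "read_responses",
    "write_responses",
    "read_profile",
    "write_profile",
    "write_result",
    "config_hash",
]

_BANK_COLS = ["item_id", "domain", "a_true", "b_true", "dif_a", "dif_b"]


def config_hash(obj) -> str:
    """Short deterministic hash of a JSON-serializable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _provenance_comment(seed, config) -> str:
    from . import __version__

    return (
        f"# acoforms v{__version__} seed={seed} "
        f"config={config_hash(config or {})}\n"
    )


def _to_csv(df: pd.DataFrame, path, seed=None, config=None) -> None:
    """CSV with an embedded provenance comment line (readers skip '#')."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_provenance_comment(seed, config))
        df.to_csv(fh, index=False)


def write_item_bank(bank: ItemBank, path, seed=None, config=None) -> None:
    _to_csv(bank.params_frame(), path, seed, config)


def read_item_bank(path) -> ItemBank:
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    missing = [c for c in _BANK_COLS[:2] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    items = []
    for _, row in df.iterrows():
        items.append(
            ItemSpec(
                item_id=str(row["item_id"]),
                domain=str(row["domain"]),
                a_true=float(row.get("a_true", np.nan)),
                b_true=float(row.get("b_true", np.nan)),
                dif_a=float(row.get("dif_a", 1.0)),
                dif_b=float(row.get("dif_b", 0.0)),
            )
        )
    return ItemBank(items=items)


def write_responses(data: ResponseData, path, seed=None, config=None) -> None:
    df = pd.DataFrame(data.responses, columns=data.item_ids)
    df.insert(0, "group", data.group if data.group is not None else "all")
    df.insert(0, "person_id", [f"p{i + 1:06d}" for i in range(data.n_persons)])
    _to_csv(df, path, seed, config)


def read_responses(path, bank: ItemBank | None = None) -> ResponseData:
    """Read a response table and reconcile its columns to the bank order."""
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    for col in ("person_id", "group"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    item_cols = [c for c in df.columns if c not in ("person_id", "group")]
    if bank is not None:
        unknown = sorted(set(item_cols) - set(bank.item_ids))
        if unknown:
            raise ValueError(f"{path}: response columns not in the bank: {unknown}")
        absent = sorted(set(bank.item_ids) - set(item_cols))
        if absent:
            raise ValueError(f"{path}: bank items missing from responses: {absent}")
        item_cols = list(bank.item_ids)
    mat = df[item_cols].to_numpy()
    bad = np.argwhere(~np.isin(mat, [0, 1]))
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"{path}: non-binary response {mat[i, j]!r} at line {i + 2}, "
            f"column {item_cols[j]!r}"
        )
    group = df["group"].to_numpy()
    if len(pd.unique(group)) == 1:
        group = None
    return ResponseData(mat, item_cols, group=group)


def write_profile(profile: CriterionProfile, path, seed=None) -> None:
    d = profile.to_dict()
    d["_provenance"] = {
        "version": __version__,
        "seed": seed,
        "config_hash": config_hash(profile.to_dict()),
    }
    Path(path).write_text(json.dumps(d, indent=2))


def read_profile(path) -> CriterionProfile:
    d = json.loads(Path(path).read_text())
    d.pop("_provenance", None)
    return CriterionProfile.from_dict(d)


def write_result(obj: dict, path, seed=None, config=None) -> None:
    """Write a result JSON with provenance (seed, config hash, version)."""
    payload = dict(obj)
    payload["_provenance"] = {
        "version": __version__,
        "seed": seed,
        "config_hash": config_hash(config or {}),
    }

    def _default(x):
        if isinstance(x, (np.integer,)):
            return int(x)
        if isinstance(x, (np.floating,)):
            return float(x)
        if isinstance(x, np.ndarray):
            return x.tolist()
        raise TypeError(f"not JSON-serializable: {type(x)}")

    Path(path).write_text(json.dumps(payload, indent=2, default=_default))


def write_calibrated_form(form, path, seed=None, config=None) -> None:
    """Export estimated item parameters: item_id, a_hat, b_hat."""
    df = pd.DataFrame(
        {"item_id": form.item_ids, "a_hat": form.a_hat, "b_hat": form.b_hat}
    )
    _to_csv(df, path, seed, config)


def write_curves(curves, path, form_names=None, seed=None, config=None) -> None:
    """Export a curve set: theta column plus one column per form."""
    names = form_names or [f"form{j + 1}" for j in range(len(curves.values_per_form))]
    if len(names) != len(curves.values_per_form):
        raise ValueError("one name per form is required")
    df = pd.DataFrame({"theta": curves.grid.nodes})
    for name, vals in zip(names, curves.values_per_form):
        df[name] = vals
    _to_csv(df, path, seed, config)
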