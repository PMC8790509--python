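"""Delimited-text formats for response matrices, form layouts and results.

Everything is plain TSV so runs are inspectable and diffable: response
matrices carry a ``group`` column and one column per item with ``NA`` for
structurally missing entries; form layouts use the same row format as the
packaged item-parameter fixtures (item_id, form, testlet, anchor, a, b or
b1..b4) plus a testlet table with the random-effect variances.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .models import (
    MISSING,
    DichotomousItemParams,
    ItemParams,
    PolytomousItemParams,
    TestletSpec,
)
from .simulate import FormPair, ResponseMatrix

NA_TOKEN = "NA"


def write_response_matrix(matrix: ResponseMatrix, path: str | Path) -> None:
    df = matrix.to_frame().astype(object)
    cols = list(matrix.item_ids)
    df[cols] = df[cols].where(df[cols] != MISSING, NA_TOKEN)
    df.to_csv(path, sep="\t", index=False)


def read_response_matrix(path: str | Path) -> ResponseMatrix:
    df = pd.read_csv(path, sep="\t", na_values=[NA_TOKEN], keep_default_na=False)
    groups = df.pop("group").to_numpy(dtype=object)
    codes = df.to_numpy(dtype=float)
    codes = np.where(np.isnan(codes), MISSING, codes).astype(np.int16)
    return ResponseMatrix(codes=codes, item_ids=tuple(df.columns), groups=np.asarray(groups))


def _items_frame(pair: FormPair) -> pd.DataFrame:
    rows = []
    for form in ("base", "new"):
        for it in pair.items_for(form):
            row = {
                "item_id": it.item_id,
                "form": form,
                "testlet": it.testlet_id or "",
                "anchor": int(it.item_id in pair.anchor_ids),
                "a": it.a,
            }
            if isinstance(it, DichotomousItemParams):
                row["b"] = it.b
            else:
                for k, v in enumerate(it.boundaries, start=1):
                    row[f"b{k}"] = v
            rows.append(row)
    return pd.DataFrame(rows)


def write_form_pair(pair: FormPair, items_path: str | Path, testlets_path: str | Path) -> None:
    _items_frame(pair).to_csv(items_path, sep="\t", index=False)
    trows = [
        {"testlet_id": s.testlet_id, "form": form, "sigma2": s.sigma2,
         "item_ids": ",".join(s.item_ids)}
        for form in ("base", "new")
        for s in pair.testlets_for(form)
    ]
    pd.DataFrame(trows).to_csv(testlets_path, sep="\t", index=False)


def read_form_pair(items_path: str | Path, testlets_path: str | Path) -> FormPair:
    idf = pd.read_csv(items_path, sep="\t", keep_default_na=False)
    tdf = pd.read_csv(testlets_path, sep="\t", keep_default_na=False)
    poly = "b1" in idf.columns

    def mk(row) -> ItemParams:
        tid = row["testlet"] or None
        if poly:
            bs = tuple(float(row[f"b{k}"]) for k in range(1, 5))
            return PolytomousItemParams(row["item_id"], float(row["a"]), bs, tid)
        return DichotomousItemParams(row["item_id"], float(row["a"]), float(row["b"]), tid)

    items = {"base": [], "new": []}
    anchors = set()
    for _, row in idf.iterrows():
        items[row["form"]].append(mk(row))
        if int(row["anchor"]):
            anchors.add(row["item_id"])
    specs = {"base": [], "new": []}
    for _, row in tdf.iterrows():
        specs[row["form"]].append(
            TestletSpec(row["testlet_id"], tuple(row["item_ids"].split(",")), float(row["sigma2"]))
        )
    return FormPair(
        base_items=tuple(items["base"]),
        new_items=tuple(items["new"]),
        anchor_ids=frozenset(anchors),
        base_testlets=tuple(specs["base"]),
        new_testlets=tuple(specs["new"]),
    )


def testlet_map_from_files(items_path: str | Path) -> dict[str, str]:
    """item_id -> testlet_id map for calibration, read from an items table."""
    idf = pd.read_csv(items_path, sep="\t", keep_default_na=False)
    return {
        row["item_id"]: row["testlet"]
        for _, row in idf.iterrows()
        if row["testlet"]
    }
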