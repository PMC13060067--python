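"""CSV ingest, screen orchestration, and result serialization.

Two input layouts are accepted:

* **long** - one row per well with columns ``block_id, drug_row, drug_col,
  conc_r, conc_c, response`` (optional ``replicate``, ``cell_line``);
  repeated wells within a block are aggregated to per-cell replicate
  summaries (mean, count, unbiased variance).
* **wide** - one matrix per file: first column holds row concentrations,
  the header row column concentrations, the body viabilities.

Responses are viabilities in [0, 1]; pass ``response_scale="inhibition"``
to ingest 1 - Y data.  Missing wells are empty fields or NA.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import DoseGrid, TransformSpec, transform_responses
from .inference import bh_fdr, wild_bootstrap_test

logger = logging.getLogger("sir")

__all__ = [
    "ScreenConfig",
    "read_dose_grids",
    "analyze_grid",
    "run_screen",
    "write_results",
]

LONG_COLUMNS = ["block_id", "drug_row", "drug_col", "conc_r", "conc_c", "response"]
TSV_COLUMNS = [
    "block_id", "drug_row", "drug_col", "cell_line", "p_value", "p_adjusted",
    "rejected", "T_obs", "S2", "S2_syn", "S2_ant", "df_null", "n_eff",
    "inflation_ratio", "B", "seed", "status",
]
_RESPONSE_SLACK = 1e-9


@dataclass
class ScreenConfig:
    """Defaults mirror the exploratory-screen settings: logit transform,
    eps = tau = 1e-6, Winsorization at the 99th percentile, B = 200."""

    transform: str = "logit"
    eps: float = 1e-6
    tau: float = 1e-6
    winsor_pct: float = 99.0
    B: int = 200
    seed: int = 0
    q: float = 0.05
    stratify_by: str | None = None
    response_scale: str = "viability"

    @property
    def spec(self) -> TransformSpec:
        return TransformSpec(name=self.transform, eps=self.eps)


def _grid_from_long(block: pd.DataFrame, block_id: str, response_scale: str) -> DoseGrid:
    vals = block["response"].astype(float)
    if response_scale == "inhibition":
        vals = 1.0 - vals
    bad = vals[(vals < -_RESPONSE_SLACK) | (vals > 1.0 + _RESPONSE_SLACK)]
    if len(bad):
        raise ValueError(
            f"block {block_id!r}: {len(bad)} responses outside [0, 1] "
            f"(worst: {bad.iloc[0]:.4g})"
        )
    df = block.assign(response=vals.clip(0.0, 1.0))
    conc_r = np.sort(df["conc_r"].unique())
    conc_c = np.sort(df["conc_c"].unique())
    g = df.groupby(["conc_r", "conc_c"])["response"]
    mean = g.mean().unstack().reindex(index=conc_r, columns=conc_c)
    count = g.count().unstack().reindex(index=conc_r, columns=conc_c)
    var = g.var(ddof=1).unstack().reindex(index=conc_r, columns=conc_c)
    return DoseGrid(
        drug_row_name=str(df["drug_row"].iloc[0]),
        drug_col_name=str(df["drug_col"].iloc[0]),
        conc_row=conc_r,
        conc_col=conc_c,
        Y=mean.to_numpy(dtype=float),
        m=np.nan_to_num(count.to_numpy(dtype=float), nan=0.0).astype(int),
        s2=var.to_numpy(dtype=float),
        block_id=str(block_id),
    )


def read_dose_grids(
    path,
    format: str = "long",
    response_scale: str = "viability",
) -> list:
    """Parse a CSV file into a list of :class:`DoseGrid`.

    Blocks that fail validation (non-numeric doses, out-of-range
    responses) are skipped with a log entry rather than aborting the whole
    file.  Doses are sorted ascending on ingest.
    """
    if response_scale not in ("viability", "inhibition"):
        raise ValueError("response_scale must be 'viability' or 'inhibition'")
    grids = []
    if format == "long":
        df = pd.read_csv(path)
        missing_cols = [c for c in LONG_COLUMNS if c not in df.columns]
        if missing_cols:
            raise ValueError(f"long CSV missing columns: {missing_cols}")
        for col in ("conc_r", "conc_c"):
            df[col] = pd.to_numeric(df[col], errors="raise")
        df = df[np.isfinite(df["response"].astype(float))]
        for block_id, block in df.groupby("block_id", sort=True):
            try:
                g = _grid_from_long(block, block_id, response_scale)
                if "cell_line" in block.columns:
                    g.cell_line = str(block["cell_line"].iloc[0])
                grids.append(g)
            except (ValueError, KeyError) as exc:
                logger.warning("skipping block %r: %s", block_id, exc)
    elif format == "wide":
        df = pd.read_csv(path, index_col=0)
        conc_c = pd.to_numeric(df.columns, errors="raise").to_numpy(dtype=float)
        conc_r = pd.to_numeric(df.index, errors="raise").to_numpy(dtype=float)
        Y = df.to_numpy(dtype=float)
        order_r, order_c = np.argsort(conc_r), np.argsort(conc_c)
        Y = Y[np.ix_(order_r, order_c)]
        if response_scale == "inhibition":
            Y = 1.0 - Y
        block_id = str(getattr(path, "stem", None) or path)
        grids.append(
            DoseGrid(
                drug_row_name="drug_row",
                drug_col_name="drug_col",
                conc_row=conc_r[order_r],
                conc_col=conc_c[order_c],
                Y=Y,
                block_id=block_id,
            )
        )
    else:
        raise ValueError("format must be 'long' or 'wide'")
    return grids


def analyze_grid(grid: DoseGrid, config: ScreenConfig | None = None, seed=None) -> dict:
    """Run the full SIR test on one grid and assemble the result record."""
    config = config or ScreenConfig()
    tg = transform_responses(
        grid, spec=config.spec, tau=config.tau, winsor_pct=config.winsor_pct
    )
    boot = wild_bootstrap_test(tg, B=config.B, seed=config.seed if seed is None else seed)
    res = boot.result
    logger.info(
        "block %s: p=%.4g T=%.4g df=%d n_eff=%d inflation=%.3f",
        grid.block_id, boot.p_value, boot.T_obs, res.df_null, res.n_eff, boot.inflation,
    )
    return {
        "block_id": grid.block_id,
        "drug_row": grid.drug_row_name,
        "drug_col": grid.drug_col_name,
        "cell_line": getattr(grid, "cell_line", ""),
        "p_value": boot.p_value,
        "T_obs": boot.T_obs,
        "S2": res.S2,
        "S2_syn": res.S2_syn,
        "S2_ant": res.S2_ant,
        "df_null": res.df_null,
        "n_eff": res.n_eff,
        "B": boot.B,
        "seed": boot.seed,
        "inflation_ratio": boot.inflation,
        "delta": res.delta.tolist(),
        "s_sir": res.s_sir.tolist(),
        "theta_iso": boot.iso.theta_iso.tolist(),
        "theta_add": boot.add.theta_add.tolist(),
        "status": "ok" if boot.n_failed == 0 else "warned",
    }


def run_screen(grids, config: ScreenConfig | None = None) -> tuple:
    """Run the SIR test across a screen of matrices.

    Per-matrix seeds are substreams of the master seed keyed by the rank
    of the (unique) block_id, so results do not depend on input order.
    Individual failures are recorded in the ``status`` column and never
    abort the batch.  Returns ``(table, records)``: a summary DataFrame
    with BH-adjusted p-values (optionally stratified) and the full
    per-matrix records including surfaces.
    """
    config = config or ScreenConfig()
    ids = [g.block_id for g in grids]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate block_ids: {dupes}")
    order = np.argsort(np.asarray(ids, dtype=object))
    records = []
    for rank, gi in enumerate(order):
        grid = grids[gi]
        sub_seed = [int(config.seed), rank]
        try:
            rec = analyze_grid(grid, config, seed=sub_seed)
        except Exception as exc:  # per-matrix failures are data, not fatal
            logger.error("block %r failed: %s", grid.block_id, exc)
            rec = {
                "block_id": grid.block_id,
                "drug_row": grid.drug_row_name,
                "drug_col": grid.drug_col_name,
                "cell_line": getattr(grid, "cell_line", ""),
                "p_value": np.nan,
                "status": f"error:{exc}",
            }
        records.append(rec)
    table = pd.DataFrame(records).reindex(columns=TSV_COLUMNS)
    ok = table["p_value"].notna().to_numpy()
    table["p_adjusted"] = np.nan
    table["rejected"] = False
    if ok.any():
        strata = None
        if config.stratify_by is not None:
            strata = table.loc[ok, config.stratify_by].to_numpy()
        rej, padj = bh_fdr(
            table.loc[ok, "p_value"].to_numpy(), q=config.q, strata=strata, B=config.B
        )
        table.loc[ok, "p_adjusted"] = padj
        table.loc[ok, "rejected"] = rej
    return table, records


def write_results(results, path, format: str = "json") -> None:
    """Serialize screen output: full records (with surfaces) as JSON, or
    the summary table as TSV with a fixed, documented column order."""
    if format == "json":
        payload = results if isinstance(results, list) else [results]
        payload = [
            dataclasses.asdict(r) if dataclasses.is_dataclass(r) else r
            for r in payload
        ]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=_jsonify)
    elif format == "tsv":
        if isinstance(results, pd.DataFrame):
            table = results.reindex(columns=TSV_COLUMNS)
        else:
            table = pd.DataFrame(list(results)).reindex(columns=TSV_COLUMNS)
        table.to_csv(path, sep="\t", index=False)
    else:
        raise ValueError("format must be 'json' or 'tsv'")


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"cannot serialize {type(obj)}")
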