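#!/usr/bin/env python
"""Plot stock and flow views of the scenario ledgers.

Reads the per-scenario ledger CSVs written by ``nursecast simulate`` (or
``replicate-paper``) and produces four PNGs: baseline stocks, baseline
flows, reform-scenario stocks, reform-scenario flows.

Usage: python scripts/make_figures.py --ledgers OUT_DIR --out FIG_DIR
"""

from __future__ import annotations

import argparse
from pathlib import Path

import pandas as pd


def load(ledger_dir: Path) -> dict[str, pd.DataFrame]:
    ledgers = {}
    for name in ("A", "B", "C"):
        path = ledger_dir / f"ledger_{name}.csv"
        if path.exists():
            ledgers[name] = pd.read_csv(path, index_col="year")
    if "A" not in ledgers:
        raise SystemExit(f"no ledger_A.csv in {ledger_dir}; run the simulation first")
    return ledgers


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--ledgers", type=Path, required=True)
    parser.add_argument("--out", type=Path, required=True)
    args = parser.parse_args()

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ledgers = load(args.ledgers)
    args.out.mkdir(parents=True, exist_ok=True)

    a = ledgers["A"]
    fig, ax = plt.subplots(figsize=(7, 4.5))
    ax.plot(a.index, a["demand_wte"], label="demand / total stock")
    ax.plot(a.index, a["stock_foreign_wte"], label="foreign educated")
    ax.plot(a.index, a["stock_domestic_wte"], label="domestically educated")
    ax.set_title("Baseline: workforce stocks (WTE)")
    ax.set_ylabel("WTE")
    ax.legend()
    fig.savefig(args.out / "baseline_stocks.png", dpi=150, bbox_inches="tight")

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for col, label in [
        ("recruitment_requirement_wte", "recruitment requirement"),
        ("replacement_wte", "replacement demand"),
        ("expansion_wte", "expansion demand"),
        ("domestic_inflow_wte", "total domestic inflow"),
        ("foreign_recruits_wte", "foreign recruitment"),
    ]:
        ax.plot(a.index, a[col], label=label)
    ax.set_title("Baseline: workforce flows (WTE/yr)")
    ax.set_ylabel("WTE per year")
    ax.legend()
    fig.savefig(args.out / "baseline_flows.png", dpi=150, bbox_inches="tight")

    reform = {k: v for k, v in ledgers.items() if k in ("B", "C")}
    if reform:
        fig, ax = plt.subplots(figsize=(7, 4.5))
        for name, ledger in reform.items():
            ax.plot(ledger.index, ledger["stock_foreign_wte"], label=f"foreign, scenario {name}")
            ax.plot(
                ledger.index, ledger["stock_domestic_wte"], "--",
                label=f"domestic, scenario {name}",
            )
        ax.set_title("Reform scenarios: workforce stocks (WTE)")
        ax.set_ylabel("WTE")
        ax.legend()
        fig.savefig(args.out / "reform_stocks.png", dpi=150, bbox_inches="tight")

        fig, ax = plt.subplots(figsize=(7, 4.5))
        for name, ledger in reform.items():
            ax.plot(ledger.index, ledger["domestic_inflow_wte"], label=f"domestic inflow {name}")
            ax.plot(
                ledger.index, ledger["recruitment_requirement_wte"], "--",
                label=f"requirement {name}",
            )
        ax.set_title("Reform scenarios: inflow vs requirement (WTE/yr)")
        ax.set_ylabel("WTE per year")
        ax.legend()
        fig.savefig(args.out / "reform_flows.png", dpi=150, bbox_inches="tight")

    for png in sorted(args.out.glob("*.png")):
        print(png)


if __name__ == "__main__":
    main()
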