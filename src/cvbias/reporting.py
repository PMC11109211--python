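"""Result persistence: tidy CSVs, a rerun manifest, and the leakage audit log.

Everything is long-format CSV so figure analogues (bias per dataset and
method, bias vs. balance, simulation curves) are one group-by away.
Plotting is optional and isolated so headless runs never fail.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from .config import RunConfig, config_hash
from .protocol import BiasRecord, ScenarioResult

__all__ = ["bias_records_frame", "write_results", "plot_simulation"]


def bias_records_frame(records) -> pd.DataFrame:
    """One row per (dataset, resampler, repeat) with both arms' metrics and
    the per-metric bias."""
    rows = []
    for rec in records:
        b = rec.bias
        rows.append(
            {
                "dataset_id": rec.dataset_id,
                "resampler": rec.resampler,
                "repeat": rec.repeat,
                **{f"correct_{k}": v for k, v in rec.correct.as_dict().items()},
                **{f"incorrect_{k}": v for k, v in rec.incorrect.as_dict().items()},
                **{f"bias_{k}": v for k, v in b.as_dict().items()},
            }
        )
    cols = ["dataset_id", "resampler", "repeat"]
    return pd.DataFrame(rows, columns=cols if not rows else None)


def _audit_lines(scenarios) -> list:
    lines = []
    for sc in scenarios:
        syn, leaky = sc.total_synthetic_in_test(), sc.total_leaky_in_test()
        verdict = "CLEAN" if syn == 0 else f"LEAKY ({leaky} test rows with a parent in train)"
        lines.append(
            f"{sc.arm:>9} arm, {sc.method}: {syn} synthetic rows across all "
            f"test folds -> {verdict}"
        )
    return lines


def write_results(
    out_dir,
    config: RunConfig | None = None,
    bias_records=None,
    summary: pd.DataFrame | None = None,
    simulation: pd.DataFrame | None = None,
    scenarios=None,
) -> dict:
    """Write whatever stages produced into ``out_dir``; returns a manifest
    (also saved as manifest.json) holding the config hash and file list so
    the run can be reproduced exactly."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = []

    def _save(df: pd.DataFrame, name: str):
        path = out / name
        df.to_csv(path, index=False)
        files.append(name)

    if bias_records is not None:
        _save(bias_records_frame(bias_records), "bias_records.csv")
    if summary is not None:
        _save(summary, "summary_by_dataset.csv")
    if simulation is not None:
        _save(simulation, "simulation.csv")
    if scenarios:
        (out / "audit.log").write_text("\n".join(_audit_lines(scenarios)) + "\n")
        files.append("audit.log")

    manifest = {
        "files": files,
        "config": config.as_dict() if config is not None else None,
        "config_hash": config_hash(config) if config is not None else None,
        "seed": config.seed if config is not None else None,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def plot_simulation(simulation: pd.DataFrame, path) -> None:
    """Mean incorrect/correct AUC vs imbalance, one line per N (headless)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for N, sub in simulation.groupby("N"):
        sub = sub.sort_values("imbalance")
        ax.plot(sub["imbalance"], sub["mean_auc_incorrect"], "o-", label=f"incorrect, N={N}")
        ax.plot(sub["imbalance"], sub["mean_auc_correct"], "s--", alpha=0.6, label=f"correct, N={N}")
    ax.axhline(0.5, color="grey", lw=0.8)
    ax.set_xlabel("imbalance ratio (100 / B)")
    ax.set_ylabel("mean test AUC")
    ax.set_ylim(0.35, 1.02)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
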