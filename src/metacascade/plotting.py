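"""Convenience writers for figure-runner outputs (CSV tables + PNG plots).

All quantitative checks read the CSV tables; the plots are for eyeballing.
"""

from __future__ import annotations

import json
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["write_figure_outputs"]


def _save_json(obj, path: Path) -> None:
    def default(o):
        if isinstance(o, np.generic):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o))
    path.write_text(json.dumps(obj, indent=2, default=default, sort_keys=True))


def _trace_table(traces: dict) -> pd.DataFrame:
    df = pd.DataFrame({str(k): np.asarray(v) for k, v in traces.items()})
    df.insert(0, "trial", np.arange(len(df)))
    return df


def write_figure_outputs(name: str, result: dict, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fig, ax = plt.subplots(figsize=(7, 4))

    if name == "fig1bc":
        _trace_table(result["traces"]).to_csv(out / f"{name}_traces.csv",
                                              index=False, float_format="%.10g")
        _trace_table(result["delta_p"]).to_csv(out / f"{name}_delta_p.csv",
                                               index=False, float_format="%.10g")
        _save_json({"adaptation": {str(k): v for k, v in
                                   result["adaptation"].items()}},
                   out / f"{name}_summary.json")
        for alpha, tr in result["traces"].items():
            ax.plot(tr, label=f"alpha={alpha}")
        ax.axvline(result["change_point"], ls=":", c="k")
        ax.set(xlabel="trial", ylabel="P(A)")
    elif name == "fig2bcd":
        pd.DataFrame({"trial": np.arange(result["delta_p"].size),
                      "delta_p": result["delta_p"]}).to_csv(
            out / f"{name}_delta_p.csv", index=False, float_format="%.10g")
        _save_json({"adaptation": {m: {str(k): v for k, v in d.items()}
                                   for m, d in result["adaptation"].items()}},
                   out / f"{name}_summary.json")
        ax.plot(result["delta_p"])
        ax.set(xlabel="trial", ylabel="delta P_A (cascade only)")
    elif name == "fig3a":
        result["summary"].to_csv(out / f"{name}_summary.csv", index=False,
                                 float_format="%.10g")
        s = result["summary"]
        ax.errorbar(np.arange(len(s)), s["median"],
                    yerr=[s["median"] - s["q25"], s["q70"] - s["median"]],
                    fmt="o-")
        ax.set(xlabel="block", ylabel="effective learning rate", yscale="log")
    elif name == "fig3bc":
        rows = []
        for task, d in result["totals"].items():
            for model, totals in d.items():
                for r, v in enumerate(np.atleast_1d(totals)):
                    rows.append({"task": task, "model": model, "run": r,
                                 "total_rewards": int(v)})
        pd.DataFrame(rows).to_csv(out / f"{name}_totals.csv", index=False)
        means = {t: {str(m): float(np.mean(v)) for m, v in d.items()}
                 for t, d in result["totals"].items()}
        _save_json(means, out / f"{name}_summary.json")
        for task, d in means.items():
            ax.plot(list(d.keys()), list(d.values()), "o-", label=task)
        ax.set(xlabel="model", ylabel="mean total rewards")
        ax.tick_params(axis="x", rotation=45)
    elif name == "fig4ab":
        _trace_table(result["delta_p"]).to_csv(out / f"{name}_delta_p.csv",
                                               index=False, float_format="%.10g")
        _save_json({"adaptation": result["adaptation"]},
                   out / f"{name}_summary.json")
        for model, tr in result["delta_p"].items():
            ax.plot(tr, label=model)
        ax.set(xlabel="trial", ylabel="delta P_A")
    elif name == "fig5ab":
        traces = {f"isi_{k}": res.p[:, :, 0].mean(axis=0)
                  for k, res in result.items()}
        _trace_table(traces).to_csv(out / f"{name}_traces.csv", index=False,
                                    float_format="%.10g")
        for label, tr in traces.items():
            ax.plot(tr, label=label)
        ax.axhline(0.9, ls=":", c="k")
        ax.set(xlabel="trial", ylabel="P(A)")
    elif name == "fig8":
        res = result["result"]
        res.to_dataframe(runs=[0]).to_csv(out / f"{name}_trials.csv",
                                          index=False, float_format="%.10g")
        _save_json({k: v for k, v in result.items() if k != "result"},
                   out / f"{name}_summary.json")
        ax.plot(res.p[0, :, 0], label="P(A)")
        ax.plot(res.surprise[0].astype(float), ".", ms=2, label="surprise")
        ax.set(xlabel="trial")
    else:
        raise ValueError(f"no writer for figure {name!r}")

    if ax.get_legend_handles_labels()[0]:
        ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(out / f"{name}.png", dpi=120)
    plt.close(fig)
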