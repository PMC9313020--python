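"""Companion plot: deposited vs re-docked conformer RMSD per control pair.

The core pipeline emits CSVs only; this script draws the scatter/line view
of the docking-reliability control from a controls CSV.

Usage: python examples/plot_control_rmsd.py CONTROLS_CSV OUT_PNG
"""
import sys

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def main(controls_csv: str, out_png: str) -> None:
    df = pd.read_csv(controls_csv)
    fig, ax = plt.subplots(figsize=(7, 4))
    x = range(1, len(df) + 1)
    ax.plot(x, df["rmsd_actual"], "o-", label="RMSD deposited", color="tab:blue")
    ax.plot(x, df["rmsd_docked"], "s--", label="RMSD docked", color="tab:orange")
    ax.set_xlabel("control pocket pair")
    ax.set_ylabel("conformer RMSD (Å)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_png, dpi=150)
    print(f"wrote {out_png}")


if __name__ == "__main__":
    main(sys.argv[1], sys.argv[2])
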