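"""Optional diagnostic plots: I-V, G-V and dG/dV relations with fits."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .traces import IVTable

__all__ = ["plot_iv", "plot_gv", "plot_dgdv"]


def plot_iv(iv: IVTable, path: str | Path, title: str = "") -> None:
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    ax.plot(iv.frame["v_step"], iv.frame["i_step"], "o-", label="I_STEP")
    ax.plot(iv.frame["v_step"], iv.frame["i_tail"], "s-", label="I_TAIL")
    ax.axhline(0, color="k", lw=0.5)
    ax.set_xlabel("V (mV)")
    ax.set_ylabel("I (pA)")
    ax.legend(frameon=False)
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_gv(iv: IVTable, path: str | Path, fit=None, title: str = "") -> None:
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    ax.plot(iv.frame["v_step"], iv.frame["g_step"], "d", label="G_STEP")
    if fit is not None:
        vv = np.linspace(iv.frame["v_step"].min(), iv.frame["v_step"].max(), 400)
        ax.plot(vv, fit.predict(vv), "-", label="Boltzmann fit")
    ax.set_xlabel("V (mV)")
    ax.set_ylabel("G (nS)")
    ax.legend(frameon=False)
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_dgdv(v, dgdv, path: str | Path, fit=None, title: str = "") -> None:
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    ax.plot(v, dgdv, "^", label="dG/dV")
    if fit is not None:
        vv = np.linspace(np.min(v), np.max(v), 400)
        ax.plot(vv, fit.predict(vv), "--", label="Gaussian fit")
    ax.set_xlabel("V (mV)")
    ax.set_ylabel("dG/dV (nS/mV)")
    ax.legend(frameon=False)
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
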