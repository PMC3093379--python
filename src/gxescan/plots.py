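"""QQ-plot rendering (thin optional layer over the numeric QQ pairs)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt

from .gcdiag import GCReport


def qq_plot(report: GCReport, path=None, title: str | None = None):
    """Observed vs expected -log10 p for both SE flavors, with identity line."""
    fig, ax = plt.subplots(figsize=(5, 5))
    qm, qr = report.qq_pairs_model, report.qq_pairs_robust
    top = max(qm[:, 0].max(), qm[:, 1].max(), qr[:, 1].max()) * 1.05
    ax.plot([0, top], [0, top], color="0.6", lw=1, zorder=1)
    ax.scatter(qm[:, 0], qm[:, 1], s=6, color="tab:red", zorder=2,
               label=f"model-based (λ = {report.lambda_model:.3f})")
    ax.scatter(qr[:, 0], qr[:, 1], s=6, color="tab:blue", zorder=3,
               label=f"robust (λ = {report.lambda_robust:.3f})")
    ax.set_xlabel("expected $-\\log_{10} p$")
    ax.set_ylabel("observed $-\\log_{10} p$")
    ax.set_xlim(0, top)
    ax.set_ylim(0, max(top, qm[:, 1].max() * 1.05))
    if title:
        ax.set_title(title)
    ax.legend(frameon=False, loc="upper left")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig
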