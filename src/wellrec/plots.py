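"""Minimal figure helpers for the evaluation outputs."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_efficacy_curve(curve, path) -> None:
    """AS−US efficacy differential against training-set size."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.plot(curve.per_k["k"], curve.per_k["mean_differential"], "o-", ms=4)
    ax.set_xlabel("training sessions (k)")
    ax.set_ylabel("AS − US benefit differential")
    ax.set_title(f"{curve.measure.upper()} efficacy differential")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_overlap(analysis, path) -> None:
    """Observed (bars) vs chance (lines) AS/US overlap against k."""
    per_k = analysis.per_k
    fig, ax = plt.subplots(figsize=(5, 3.5))
    width = 0.27
    for offset, (obs, exp, label) in enumerate(
        [
            ("observed_ge1", "expected_ge1", ">=1"),
            ("observed_ge2", "expected_ge2", ">=2"),
            ("observed_eq3", "expected_eq3", "=3"),
        ]
    ):
        ax.bar(per_k["k"] + (offset - 1) * width, per_k[obs], width=width,
               alpha=0.7, label=f"observed {label}")
        ax.plot(per_k["k"], per_k[exp], "--", lw=1.2, label=f"chance {label}")
    ax.set_xlabel("training sessions (k)")
    ax.set_ylabel("proportion of users")
    ax.set_title(f"{analysis.measure.upper()} AS/US overlap")
    ax.legend(fontsize=7, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
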