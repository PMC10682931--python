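"""Minimal rendering of attributions: a horizontal bar chart of top-k weights."""

from __future__ import annotations

from .attribution import AttributionVector, top_k


def plot_top_k(attr: AttributionVector, k: int, ax=None, out=None):
    """Horizontal bars of the k largest |weights|, signed, largest on top."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = top_k(attr, k)
    idx = {f: j for j, f in enumerate(attr.feature_names)}
    values = [attr.weights[idx[f]] for f in names]
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.4 * k + 1))
    ax.barh(
        range(len(names))[::-1],
        values,
        color=["#c0392b" if v >= 0 else "#2980b9" for v in values],
    )
    ax.set_yticks(range(len(names))[::-1])
    ax.set_yticklabels(names)
    ax.axvline(0.0, color="black", linewidth=0.8)
    ax.set_xlabel(f"{attr.method} weight")
    if out is not None:
        ax.figure.savefig(out, bbox_inches="tight")
    return ax
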