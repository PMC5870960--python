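"""ENC-plot and PR2-plot figures.

Both take the per-gene index table produced by
:func:`cubkit.indices.per_gene_index_table`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .indices import expected_enc


def enc_plot(per_gene: pd.DataFrame, ax=None, **scatter_kw):
    """Scatter of per-gene ENC against GC3s with the expected-ENC curve."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    s = np.linspace(0.0, 1.0, 201)
    ax.plot(s, expected_enc(s), color="black", lw=1.2, label="expected ENC")
    kw = {"s": 8, "alpha": 0.5}
    kw.update(scatter_kw)
    ax.scatter(per_gene["GC3s"], per_gene["ENC"], **kw)
    ax.set_xlabel("GC3s")
    ax.set_ylabel("ENC")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 70)
    ax.legend(frameon=False)
    return ax


def pr2_plot(per_gene: pd.DataFrame, ax=None, **scatter_kw):
    """PR2-bias scatter with the (0.5, 0.5) parity cross-hairs."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    kw = {"s": 8, "alpha": 0.5}
    kw.update(scatter_kw)
    ax.scatter(per_gene["PR2_x"], per_gene["PR2_y"], **kw)
    ax.axhline(0.5, color="black", lw=0.8)
    ax.axvline(0.5, color="black", lw=0.8)
    ax.set_xlabel("G3s / (G3s + C3s)")
    ax.set_ylabel("A3s / (A3s + T3s)")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    return ax
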