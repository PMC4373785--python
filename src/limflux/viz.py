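"""Hypergraph rendering of sub-networks with flux-proportional edge widths.

Metabolites are drawn as labelled boxes; each drawn reaction becomes a
hyperedge connecting its drawn substrates to its drawn products, with

* edge width  = max(min_width, width_scale * |flux|)  (points),
* arrowheads pointing in the direction of net flux (reversed for negative
  fluxes, which are drawn in red with the negative value printed),
* labels showing the reaction id and the flux rounded to two decimals.

Metabolites omitted from the plot spec are silently not drawn, so a
hyperedge may connect only a subset of a reaction's participants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.patches import FancyArrowPatch

from .fba import FluxVector
from .model import MetabolicModel

__all__ = ["PlotSpec", "render_hypergraph"]


@dataclass
class PlotSpec:
    """What to draw and how to scale edge widths."""

    reaction_ids: list[str]
    metabolite_ids: list[str]
    layout: str = "layered"
    width_scale: float = 20.0  # points per mmol/min
    min_width: float = 0.5     # points; keeps zero fluxes visible

    def __post_init__(self):
        if self.width_scale <= 0:
            raise ValueError("width_scale must be > 0")
        if self.layout not in ("layered", "force"):
            raise ValueError(f"unknown layout {self.layout!r}")


def _layered_positions(metabolite_ids):
    """Vertical pathway reading: listed metabolites run top to bottom, in
    two staggered columns when the list is long."""
    n = len(metabolite_ids)
    pos = {}
    ncol = 1 if n <= 8 else 2
    per = (n + ncol - 1) // ncol
    for i, mid in enumerate(metabolite_ids):
        col, row = divmod(i, per)
        pos[mid] = (col * 3.0 + (0.4 if row % 2 else 0.0), -row * 1.0)
    return pos


def _force_positions(metabolite_ids, edges, seed=0):
    """Simple spring layout: attraction along hyperedges, global repulsion."""
    n = len(metabolite_ids)
    idx = {m: i for i, m in enumerate(metabolite_ids)}
    rng = np.random.default_rng(seed)
    xy = rng.standard_normal((n, 2))
    pairs = [(idx[a], idx[b]) for a, b in edges if a in idx and b in idx]
    for _ in range(100):
        disp = np.zeros_like(xy)
        delta = xy[:, None, :] - xy[None, :, :]
        dist2 = np.sum(delta**2, axis=-1) + 1e-6
        disp += np.sum(delta / dist2[..., None], axis=1) * 0.5
        for a, b in pairs:
            d = xy[a] - xy[b]
            disp[a] -= 0.1 * d
            disp[b] += 0.1 * d
        xy += 0.05 * disp
    return {m: tuple(xy[idx[m]]) for m in metabolite_ids}


def render_hypergraph(
    model: MetabolicModel,
    fluxes: FluxVector,
    spec: PlotSpec,
    path,
) -> None:
    """Draw the selected sub-network with flux-proportional hyperedges.

    SVG is the canonical output (edge widths are testable as stroke-width
    attributes); PNG or PDF follow from the file suffix.
    """
    drawn_mets = [m for m in spec.metabolite_ids if any(
        mm.id == m for mm in model.metabolites)]
    rxns = [model.reaction(rid) for rid in spec.reaction_ids]
    rxns = [r for r in rxns if any(m in drawn_mets for m in r.stoichiometry)]
    if not drawn_mets or not rxns:
        raise ValueError("nothing to draw: empty drawable metabolite/reaction set")

    if spec.layout == "layered":
        pos = _layered_positions(drawn_mets)
    else:
        edges = []
        for r in rxns:
            subs = [m for m in r.substrates if m in drawn_mets]
            prods = [m for m in r.products if m in drawn_mets]
            edges.extend((a, b) for a in subs for b in prods)
        pos = _force_positions(drawn_mets, edges)

    fig, ax = plt.subplots(figsize=(7, max(4, 0.6 * len(drawn_mets))))
    ax.axis("off")
    for mid, (x, y) in pos.items():
        ax.text(x, y, mid, ha="center", va="center", fontsize=8,
                bbox=dict(boxstyle="round,pad=0.3", fc="0.9", ec="0.4"))

    def centroid(mids, fallback):
        pts = [pos[m] for m in mids if m in pos]
        if not pts:
            return fallback
        return tuple(np.mean(pts, axis=0))

    for r in rxns:
        flux = fluxes.values.get(r.id, 0.0)
        width = max(spec.min_width, spec.width_scale * abs(flux))
        subs = [m for m in r.substrates if m in pos]
        prods = [m for m in r.products if m in pos]
        start = centroid(subs, None) or centroid(prods, (0, 0))
        end = centroid(prods, None) or start
        if start == end:
            end = (start[0] + 0.8, start[1] - 0.3)
        if flux < 0:
            # reaction runs in reverse relative to its forward definition
            start, end = end, start
            color = "red"
        else:
            color = "black"
        arrow = FancyArrowPatch(
            start, end, arrowstyle="-|>", mutation_scale=10 + 2 * width,
            linewidth=width, color=color, shrinkA=16, shrinkB=16,
            gid=f"edge_{r.id}",
        )
        ax.add_patch(arrow)
        mx, my = (np.asarray(start) + np.asarray(end)) / 2
        ax.text(mx + 0.12, my, f"{r.id}\n{flux:.2f}", fontsize=7, color=color)

    ax.relim()
    ax.autoscale_view()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
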