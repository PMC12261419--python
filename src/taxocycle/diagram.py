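"""Biogeochemical cycle diagrams: templates, projection, rendering.

A cycle diagram is a compound-transformation graph: nodes are pools
(CO2, CH4, acetate, SO4^2-, ...) and each edge is a coarse-grained
function converting substrate to product.  Templates are packaged data,
not logic: an SVG body paired with a TSV edge map (``function_name``,
``anchor_id``, ``substrate``, ``product``) whose anchors are ``<text>``
element ids inside the SVG.  Rendering replaces each anchor's text with
the function's weight formatted as a whole percentage (half-up
rounding); zero weights are restyled grey rather than omitted, so absent
functions are visibly absent.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .community import CommunityProfile

__all__ = [
    "DiagramEdge",
    "CycleDiagram",
    "ProjectedDiagram",
    "DiagramError",
    "load_template",
    "packaged_template",
    "packaged_cycles",
    "project_profile",
    "format_weight",
    "render",
    "polar_summary",
    "heatmap_table",
    "plot_heatmap",
    "plot_polar",
]

#: Fraction below which a function is hidden from summary plots (at-least-one
#: sample above threshold retains the function for every column).
DEFAULT_MIN_DISPLAY = 0.10


class DiagramError(ValueError):
    """Template/projection inconsistencies."""


@dataclass(frozen=True)
class DiagramEdge:
    function_name: str
    anchor_id: str
    substrate: str
    product: str


@dataclass(frozen=True)
class CycleDiagram:
    name: str
    svg_text: str
    edges: tuple[DiagramEdge, ...]

    @property
    def nodes(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for e in self.edges:
            seen.setdefault(e.substrate)
            seen.setdefault(e.product)
        return tuple(seen)


@dataclass(frozen=True)
class ProjectedDiagram:
    diagram: CycleDiagram
    weights: Mapping[str, float]  # function_name -> fraction in [0, 1]
    mode: str  # "occurrence" | "abundance"
    sample_id: str


def _anchor_pattern(anchor_id: str) -> re.Pattern[str]:
    return re.compile(
        rf'(<text[^>]*\bid="{re.escape(anchor_id)}"[^>]*>)([^<]*)(</text>)'
    )


def load_template(svg_path: str | Path, edges_path: str | Path | None = None) -> CycleDiagram:
    """Load an SVG template and its edge map (``<stem>_edges.tsv`` by default)."""
    svg_path = Path(svg_path)
    if edges_path is None:
        edges_path = svg_path.with_name(svg_path.stem + "_edges.tsv")
    svg_text = svg_path.read_text()
    edges: list[DiagramEdge] = []
    for lineno, line in enumerate(Path(edges_path).read_text().splitlines(), start=1):
        if not line.strip() or (lineno == 1 and line.startswith("function_name")):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 4:
            raise DiagramError(f"{edges_path}: line {lineno}: expected 4 columns")
        edge = DiagramEdge(*fields[:4])
        if _anchor_pattern(edge.anchor_id).search(svg_text) is None:
            raise DiagramError(
                f"{edges_path}: function {edge.function_name!r} maps to anchor "
                f"{edge.anchor_id!r}, which is absent from {svg_path.name}"
            )
        edges.append(edge)
    return CycleDiagram(name=svg_path.stem, svg_text=svg_text, edges=tuple(edges))


def packaged_cycles() -> tuple[str, ...]:
    return ("carbon", "nitrogen", "sulfur")


def packaged_template(cycle: str) -> CycleDiagram:
    if cycle not in packaged_cycles():
        raise DiagramError(f"no packaged template for cycle {cycle!r}")
    base = resources.files("taxocycle.data").joinpath("templates")
    with resources.as_file(base.joinpath(f"{cycle}.svg")) as svg_path:
        with resources.as_file(base.joinpath(f"{cycle}_edges.tsv")) as edges_path:
            return load_template(svg_path, edges_path)


def project_profile(
    profiles: Mapping[str, CommunityProfile] | CommunityProfile,
    diagram: CycleDiagram,
    mode: str = "occurrence",
    sample: str | None = None,
) -> ProjectedDiagram:
    """Weight each diagram edge with the sample's profile value.

    Functions absent from the diagram are ignored; diagram edges whose
    function has no profile value are weighted 0.
    """
    if mode not in ("occurrence", "abundance"):
        raise DiagramError(f"unknown weight mode {mode!r}")
    if isinstance(profiles, CommunityProfile):
        profile = profiles
        if sample is not None and sample != profile.sample_id:
            raise DiagramError(f"unknown sample id {sample!r}")
    else:
        if sample is None:
            raise DiagramError("sample id required with a profile mapping")
        if sample not in profiles:
            raise DiagramError(f"unknown sample id {sample!r}")
        profile = profiles[sample]
    values = profile.occurrence if mode == "occurrence" else profile.abundance
    if values is None:
        raise DiagramError("abundance mode requested but the profile has no abundances")
    weights = {
        e.function_name: float(values.get(e.function_name, 0.0)) for e in diagram.edges
    }
    return ProjectedDiagram(
        diagram=diagram, weights=weights, mode=mode, sample_id=profile.sample_id
    )


def format_weight(value: float) -> str:
    """Whole-percent label with half-up rounding (0.005 -> ``1%``)."""
    pct = Decimal(repr(value)) * Decimal(100)
    return f"{pct.quantize(Decimal(1), rounding=ROUND_HALF_UP)}%"


def render(projected: ProjectedDiagram, out_path: str | Path) -> Path:
    """Write the projected diagram as SVG; byte-stable for identical inputs."""
    text = projected.diagram.svg_text
    for edge in projected.diagram.edges:
        weight = projected.weights.get(edge.function_name, 0.0)
        label = format_weight(weight)

        def _sub(m: re.Match[str], label: str = label, weight: float = weight) -> str:
            opening = m.group(1)
            if weight == 0.0 and 'class="weight"' in opening:
                opening = opening.replace('class="weight"', 'class="weight zero"')
            return f"{opening}{label}{m.group(3)}"

        text = _anchor_pattern(edge.anchor_id).sub(_sub, text, count=1)
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    out_path.write_text(text)
    return out_path


# ---------------------------------------------------------------------------
# Summary tables and plots
# ---------------------------------------------------------------------------

def _profile_frame(
    profiles: Mapping[str, CommunityProfile],
    samples: Sequence[str] | None = None,
    mode: str | None = None,
) -> tuple[pd.DataFrame, str]:
    keys = sorted(profiles) if samples is None else list(samples)
    for s in keys:
        if s not in profiles:
            raise DiagramError(f"unknown sample id {s!r}")
    if mode is None:
        mode = (
            "abundance"
            if all(profiles[s].abundance is not None for s in keys)
            else "occurrence"
        )
    cols = {}
    for s in keys:
        p = profiles[s]
        series = p.occurrence if mode == "occurrence" else p.abundance
        if series is None:
            raise DiagramError(f"sample {s!r} has no abundance values")
        cols[s] = series
    df = pd.DataFrame(cols)
    df.index.name = "function"
    return df, mode


def polar_summary(
    profiles: Mapping[str, CommunityProfile],
    min_display: float = DEFAULT_MIN_DISPLAY,
    samples: Sequence[str] | None = None,
    mode: str | None = None,
) -> pd.DataFrame:
    """Function x sample table restricted to displayed functions.

    A function is retained iff its value reaches ``min_display`` in at
    least one selected sample; retained functions keep all columns.
    ``min_display=0`` is the identity on the function set.
    """
    if not 0.0 <= min_display <= 1.0:
        raise DiagramError("min_display must lie in [0, 1]")
    df, _ = _profile_frame(profiles, samples, mode)
    keep = (df >= min_display).any(axis=1)
    return df.loc[keep]


def heatmap_table(
    profiles: Mapping[str, CommunityProfile],
    samples: Sequence[str] | None = None,
    mode: str | None = None,
) -> pd.DataFrame:
    """All functions x samples (the unrestricted companion of polar_summary)."""
    df, _ = _profile_frame(profiles, samples, mode)
    return df


def plot_heatmap(table: pd.DataFrame, out_path: str | Path) -> Path:
    """Pixel output is presentation only; the tested surface is the table."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import seaborn as sns

    fig, ax = plt.subplots(
        figsize=(2 + 0.8 * len(table.columns), 1 + 0.4 * max(len(table), 1))
    )
    if len(table):
        sns.heatmap(table, vmin=0.0, vmax=1.0, annot=True, fmt=".2f", cmap="viridis", ax=ax)
    ax.set_xlabel("sample")
    fig.tight_layout()
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path


def plot_polar(table: pd.DataFrame, out_path: str | Path) -> Path:
    import math

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig = plt.figure(figsize=(7, 7))
    ax = fig.add_subplot(projection="polar")
    n = len(table)
    if n:
        angles = [2 * math.pi * k / n for k in range(n)] + [0.0]
        for sample in table.columns:
            values = list(table[sample]) + [float(table[sample].iloc[0])]
            ax.plot(angles, values, label=str(sample))
            ax.fill(angles, values, alpha=0.15)
        ax.set_xticks(angles[:-1])
        ax.set_xticklabels(list(table.index), fontsize=8)
    ax.set_ylim(0, 1)
    ax.legend(loc="upper right", bbox_to_anchor=(1.25, 1.1))
    fig.tight_layout()
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path
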