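"""Rendering of a profile as a multi-page printable PDF.

Page 1 is a map of the country (Voronoi cells of the municipality points
stand in for municipal polygons, clipped to the bounding box) with the
catchment area filled ochre, the location marked by a black dot and an
optional comparator district shaded green.  Page 2 shows all 35 indicators
as one compact boxplot row each, grouped under the five domain headings:
whiskers span the total range of the cleaned district values, the box spans
the 25th to 75th percentile, a tick marks the median, a red line the
national value, a circle the catchment value and a square the comparator
district's value.  Page 3 is the tabular results (values, absolute counts,
rank), pages 4-5 the indicator definitions.  The page-3 table is also
emitted as a sidecar CSV at full precision — display rounding happens only
in the PDF layer.

Rendering is a pure view: the profile object is never modified, and with a
frozen timestamp two renders of the same profile are byte-identical.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass
from pathlib import Path

import matplotlib
matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd
from matplotlib.backends.backend_pdf import PdfPages
from matplotlib.patches import Rectangle
from shapely.geometry import MultiPoint, Point, box
from shapely.ops import voronoi_diagram
from shapely.strtree import STRtree

from .aggregation import IndicatorResult
from .catalogue import Catalogue
from .profiles import ProfileResult
from .synthetic_country import CountryFixture

A4_PORTRAIT = (8.27, 11.69)


@dataclass(frozen=True)
class ReportStyle:
    """Colours, glyphs and page settings of the rendered report."""

    catchment_fill: str = "#d9a441"      # ochre
    location_marker: str = "black"
    comparator_fill: str = "#3a9e5f"     # green
    national_line: str = "red"
    catchment_glyph: str = "o"           # circle = catchment value
    comparator_glyph: str = "s"          # square = comparator district
    background_fill: str = "#e8e8e8"
    page_size: tuple[float, float] = A4_PORTRAIT
    font_size: float = 7.0
    decimals: int = 1

    def __post_init__(self) -> None:
        if self.catchment_glyph == self.comparator_glyph:
            raise ValueError("catchment and comparator glyphs must be distinct")


@dataclass(frozen=True)
class ReportSummary:
    """What was written: paths and structural counts (used for validation)."""

    pdf_path: Path
    csv_path: Path
    page_count: int
    table_rows: int


def _is_missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


def _fmt(value, units: str, decimals: int) -> str:
    if _is_missing(value):
        return "n/a"
    if "minutes" in units:
        return f"{value:.0f}"
    if units in ("inhabitants", "pharmacies") or units.startswith("inhabitants per"):
        return f"{value:,.0f}"
    return f"{value:,.{decimals}f}"


# --------------------------------------------------------------------------
# page 1: map


def _voronoi_cells(fixture: CountryFixture) -> dict[str, object]:
    """Clipped Voronoi cell polygon per municipality (stand-in boundaries)."""
    xs = fixture.municipalities["x"].to_numpy()
    ys = fixture.municipalities["y"].to_numpy()
    ids = fixture.municipality_ids
    pad_x = 0.02 * (xs.max() - xs.min() + 1.0)
    pad_y = 0.02 * (ys.max() - ys.min() + 1.0)
    bbox = box(xs.min() - pad_x, ys.min() - pad_y, xs.max() + pad_x, ys.max() + pad_y)
    diagram = voronoi_diagram(MultiPoint(list(zip(xs, ys))), envelope=bbox)
    cells = [g for g in diagram.geoms]
    tree = STRtree(cells)
    out: dict[str, object] = {}
    for mid, x, y in zip(ids, xs, ys):
        hits = tree.query(Point(x, y), predicate="within")
        if len(hits):
            out[mid] = cells[int(hits[0])].intersection(bbox)
    return out


def _draw_polygon(ax, poly, **kwargs) -> None:
    geoms = poly.geoms if hasattr(poly, "geoms") else [poly]
    for g in geoms:
        if g.is_empty or not hasattr(g, "exterior"):
            continue
        xs, ys = g.exterior.xy
        ax.fill(xs, ys, **kwargs)


def _render_map_page(pdf: PdfPages, profile: ProfileResult, fixture: CountryFixture,
                     style: ReportStyle) -> None:
    fig, ax = plt.subplots(figsize=style.page_size)
    comparator = profile.request.comparator_district_id
    comparator_members = set(
        fixture.district_members().get(comparator, [])) if comparator else set()
    if len(fixture.municipalities) >= 4:
        cells = _voronoi_cells(fixture)
        for mid, poly in cells.items():
            if mid in profile.catchment:
                colour = style.catchment_fill
            elif mid in comparator_members:
                colour = style.comparator_fill
            else:
                colour = style.background_fill
            _draw_polygon(ax, poly, facecolor=colour, edgecolor="white", linewidth=0.2)
    else:
        ax.scatter(fixture.municipalities["x"], fixture.municipalities["y"],
                   s=6, color=style.background_fill)
    loc = fixture.municipalities.set_index("municipality_id").loc[profile.request.location_id]
    ax.plot([loc["x"]], [loc["y"]], marker="o", color=style.location_marker,
            markersize=6, gid="location-marker")
    ax.set_aspect("equal")
    ax.set_axis_off()
    title = (
        f"Regional health care profile — location {profile.request.location_id}, "
        f"{profile.request.cutoff_minutes:g}-min car travel-time catchment"
    )
    if comparator:
        title += f", comparator district {comparator}"
    ax.set_title(title, fontsize=style.font_size + 3)
    ax.annotate(
        f"catchment: {len(profile.catchment)} municipalities (ochre); location: black dot"
        + ("; comparator district: green" if comparator else ""),
        xy=(0.5, 0.02), xycoords="figure fraction", ha="center", fontsize=style.font_size,
    )
    pdf.savefig(fig)
    plt.close(fig)


# --------------------------------------------------------------------------
# page 2: boxplot panel


def render_boxplot_panel(
    results: list[IndicatorResult] | tuple[IndicatorResult, ...],
    style: ReportStyle,
    cat: Catalogue,
) -> plt.Figure:
    """One boxplot row per indicator, grouped under domain headers.

    Every drawn glyph carries a ``gid`` of the form ``<role>::<indicator_id>``
    (roles: whisker, boxq, median, national, catchment, comparator) so its
    coordinates can be read back programmatically.
    """
    if not results:
        raise ValueError("results must not be empty")
    defs = {d.indicator_id: d for d in cat}
    n = len(results)
    n_domains = len(cat.domain_order)
    fig = plt.figure(figsize=style.page_size)
    # one slot per indicator row plus one per domain header
    total = n + n_domains
    top, bottom = 0.96, 0.04
    slot = (top - bottom) / total
    pos = 0
    last_domain = None
    for res in results:
        defn = defs[res.indicator_id]
        if defn.domain != last_domain:
            y = top - (pos + 0.7) * slot
            fig.text(0.02, y, defn.domain, fontsize=style.font_size + 2,
                     fontweight="bold", gid=f"domain-header::{defn.domain}")
            last_domain = defn.domain
            pos += 1
        ax = fig.add_axes([0.42, top - (pos + 0.9) * slot, 0.54, slot * 0.72])
        _draw_indicator_row(ax, res, defn, style)
        fig.text(0.03, top - (pos + 0.55) * slot, defn.label[:72],
                 fontsize=style.font_size - 1.5, va="center")
        pos += 1
    return fig


def _draw_indicator_row(ax, res: IndicatorResult, defn, style: ReportStyle) -> None:
    d = res.distribution
    span = d.maximum - d.minimum
    pad = 0.08 * span if span > 0 else max(abs(d.median), 1.0) * 0.1
    lo, hi = d.minimum - pad, d.maximum + pad
    for v in (res.catchment_value, res.comparator_value, d.national_value):
        if not _is_missing(v):
            lo, hi = min(lo, v - pad), max(hi, v + pad)
    iid = res.indicator_id
    ax.plot([d.minimum, d.maximum], [0.5, 0.5], color="0.4", linewidth=0.8,
            gid=f"whisker::{iid}", zorder=1)
    ax.add_patch(Rectangle((d.q25, 0.2), max(d.q75 - d.q25, 0), 0.6,
                           facecolor="0.82", edgecolor="0.4", linewidth=0.6,
                           gid=f"boxq::{iid}", zorder=2))
    ax.plot([d.median, d.median], [0.2, 0.8], color="0.2", linewidth=1.0,
            gid=f"median::{iid}", zorder=3)
    ax.plot([d.national_value, d.national_value], [0.0, 1.0],
            color=style.national_line, linewidth=1.0, gid=f"national::{iid}", zorder=4)
    if not _is_missing(res.catchment_value):
        ax.plot([res.catchment_value], [0.5], marker=style.catchment_glyph,
                markersize=4.5, color=style.catchment_fill,
                markeredgecolor="black", markeredgewidth=0.5, linestyle="none",
                gid=f"catchment::{iid}", zorder=5)
    else:
        ax.text(0.99, 0.5, "n/a", transform=ax.transAxes, fontsize=style.font_size - 2,
                ha="right", va="center")
    if not _is_missing(res.comparator_value):
        ax.plot([res.comparator_value], [0.5], marker=style.comparator_glyph,
                markersize=4.0, color=style.comparator_fill,
                markeredgecolor="black", markeredgewidth=0.5, linestyle="none",
                gid=f"comparator::{iid}", zorder=5)
    ax.set_xlim(lo, hi)
    ax.set_ylim(0, 1)
    ax.set_yticks([])
    ax.tick_params(axis="x", labelsize=style.font_size - 2, length=2)
    for side in ("left", "right", "top"):
        ax.spines[side].set_visible(False)


# --------------------------------------------------------------------------
# page 3: results table (+ sidecar CSV)


def profile_table(profile: ProfileResult, cat: Catalogue) -> pd.DataFrame:
    """Full-precision table of all indicator results (the sidecar CSV)."""
    defs = {d.indicator_id: d for d in cat}
    rows = []
    for res in profile.results:
        d = res.distribution
        defn = defs[res.indicator_id]
        rows.append(
            {
                "indicator_id": res.indicator_id,
                "label": defn.label,
                "domain": defn.domain,
                "units": defn.units,
                "catchment_value": res.catchment_value,
                "absolute_numerator": res.absolute_numerator,
                "absolute_denominator": res.absolute_denominator,
                "district_min": d.minimum,
                "district_q25": d.q25,
                "district_median": d.median,
                "district_q75": d.q75,
                "district_max": d.maximum,
                "national_value": d.national_value,
                "rank": res.rank,
                "comparator_value": res.comparator_value,
                "cleaned_flag": res.cleaned_flag,
            }
        )
    return pd.DataFrame(rows)


def _render_table_page(pdf: PdfPages, profile: ProfileResult, cat: Catalogue,
                       style: ReportStyle) -> int:
    defs = {d.indicator_id: d for d in cat}
    has_comp = profile.request.comparator_district_id is not None
    header = ["Indicator", "Catchment", "Absolute", "Median (districts)", "National", "Rank"]
    if has_comp:
        header.append("Comparator")
    cell_rows = []
    for res in profile.results:
        defn = defs[res.indicator_id]
        if res.absolute_numerator is None:
            absolute = "–"
        elif res.absolute_denominator is None:
            absolute = f"{res.absolute_numerator:,.0f}"
        else:
            absolute = f"{res.absolute_numerator:,.0f} / {res.absolute_denominator:,.0f}"
        row = [
            defn.label[:58],
            _fmt(res.catchment_value, defn.units, style.decimals),
            absolute,
            _fmt(res.distribution.median, defn.units, style.decimals),
            _fmt(res.distribution.national_value, defn.units, style.decimals),
            "n/a" if res.rank is None else str(res.rank),
        ]
        if has_comp:
            row.append(_fmt(res.comparator_value, defn.units, style.decimals))
        cell_rows.append(row)
    fig, ax = plt.subplots(figsize=style.page_size)
    ax.set_axis_off()
    ax.set_title("Indicator results and absolute values for the catchment area",
                 fontsize=style.font_size + 3)
    table = ax.table(cellText=cell_rows, colLabels=header, loc="center",
                     cellLoc="right", colLoc="center")
    table.auto_set_font_size(False)
    table.set_fontsize(style.font_size - 1)
    table.scale(1.0, 0.62)
    for (r, c), cell in table.get_celld().items():
        cell.set_linewidth(0.3)
        if c == 0:
            cell.set_text_props(ha="left")
            cell.set_width(0.42)
    pdf.savefig(fig)
    plt.close(fig)
    return len(cell_rows)


# --------------------------------------------------------------------------
# pages 4-5: indicator definitions


def _render_definition_pages(pdf: PdfPages, cat: Catalogue, style: ReportStyle) -> None:
    defs = list(cat)
    half = (len(defs) + 1) // 2
    for chunk, page_no in ((defs[:half], 1), (defs[half:], 2)):
        fig = plt.figure(figsize=style.page_size)
        fig.text(0.05, 0.97, f"Indicator definitions ({page_no}/2)",
                 fontsize=style.font_size + 3, fontweight="bold")
        y = 0.93
        for defn in chunk:
            flags = []
            if defn.source_granularity.value == "supra_municipal":
                flags.append("interpolated from a supra-municipal level")
            if defn.linkage_flag:
                flags.append("person-level record linkage")
            suffix = f"  [{'; '.join(flags)}]" if flags else ""
            fig.text(0.05, y, f"{defn.label} ({defn.units})",
                     fontsize=style.font_size, fontweight="bold")
            body = defn.definition_text + suffix
            wrapped = _wrap(body, 118)
            for line in wrapped:
                y -= 0.0135
                fig.text(0.06, y, line, fontsize=style.font_size - 1)
            y -= 0.028
        pdf.savefig(fig)
        plt.close(fig)


def _wrap(text: str, width: int) -> list[str]:
    words, lines, cur = text.split(), [], ""
    for w in words:
        if len(cur) + len(w) + 1 > width:
            lines.append(cur)
            cur = w
        else:
            cur = f"{cur} {w}".strip()
    if cur:
        lines.append(cur)
    return lines


# --------------------------------------------------------------------------
# the full report


def render_pdf(
    profile: ProfileResult,
    cat: Catalogue,
    fixture: CountryFixture,
    out: str | Path,
    style: ReportStyle | None = None,
    timestamp: _dt.datetime | None = None,
) -> ReportSummary:
    """Render the complete multi-page profile PDF plus the sidecar CSV.

    ``timestamp`` freezes the PDF creation/modification metadata, making the
    output byte-reproducible; it defaults to the profile's generation time.
    """
    style = style or ReportStyle()
    out = Path(out)
    ts = timestamp or profile.generated_at
    csv_path = out.with_suffix(".csv")
    table = profile_table(profile, cat)
    metadata = {
        "Title": f"Regional health care profile {profile.request.location_id}",
        "Subject": f"{profile.request.cutoff_minutes:g}-minute car travel-time catchment",
        "CreationDate": ts,
        "ModDate": ts,
    }
    with PdfPages(out, metadata=metadata) as pdf:
        _render_map_page(pdf, profile, fixture, style)
        fig = render_boxplot_panel(profile.results, style, cat)
        pdf.savefig(fig)
        plt.close(fig)
        n_rows = _render_table_page(pdf, profile, cat, style)
        _render_definition_pages(pdf, cat, style)
        page_count = pdf.get_pagecount()
    table.to_csv(csv_path, index=False)
    return ReportSummary(pdf_path=out, csv_path=csv_path, page_count=page_count,
                         table_rows=n_rows)
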