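"""Plain-text and static-HTML territory reports.

The report shows the per-theme color frequency table — the territory
"profile" — in the same traffic-light banding the instrument uses for a
single dwelling, plus the class counts and score/completion statistics.
"""

from __future__ import annotations

from html import escape

from .grid import GridDefinition
from .stock import COLOR_BINS, StockSummary

_HEX = {
    "green": "#2e7d32",
    "yellow": "#f9a825",
    "orange": "#ef6c00",
    "red": "#c62828",
    "blank": "#9e9e9e",
}


def _fmt(x) -> str:
    if x is None:
        return "n/a"
    return f"{x:.3f}" if isinstance(x, float) else str(x)


def render_text_report(summary: StockSummary, grid: GridDefinition) -> str:
    lines = [
        f"Domiscore territory report — grid {summary.metadata.get('grid_version', '?')}",
        f"dwellings: {summary.n_dwellings}   penalty_mode: "
        f"{summary.metadata.get('penalty_mode', '?')}",
        "",
        "class counts: "
        + "  ".join(f"{c}={summary.class_counts[c]}" for c in ("green", "yellow", "orange", "red")),
        "global score: "
        + "  ".join(f"{k}={_fmt(v)}" for k, v in summary.global_score_stats.items()),
        "completion:   "
        + "  ".join(f"{k}={_fmt(v)}" for k, v in summary.completion_stats.items()),
        f"alerts: {summary.alert_count}",
        "",
        "theme profile (counts per color):",
    ]
    labels = {c.id: c.label for c in grid.categories}
    width = max(len(labels[c]) for c in summary.theme_color_frequencies)
    header = " " * (width + 2) + "".join(f"{c:>8}" for c in COLOR_BINS)
    lines.append(header)
    for cid, freq in summary.theme_color_frequencies.items():
        lines.append(
            f"{labels[cid]:<{width}}  " + "".join(f"{freq[c]:>8}" for c in COLOR_BINS)
        )
    return "\n".join(lines) + "\n"


def render_html_report(summary: StockSummary, grid: GridDefinition) -> str:
    """A single static HTML file; no external assets."""
    labels = {c.id: c.label for c in grid.categories}
    rows = []
    for cid, freq in summary.theme_color_frequencies.items():
        cells = "".join(
            f'<td style="background:{_HEX[c]};color:#fff;text-align:center">{freq[c]}</td>'
            for c in COLOR_BINS
        )
        rows.append(f"<tr><td>{escape(labels[cid])}</td>{cells}</tr>")
    classes = "".join(
        f'<td style="background:{_HEX[c]};color:#fff;text-align:center">'
        f"{summary.class_counts[c]}</td>"
        for c in ("green", "yellow", "orange", "red")
    )
    stats = "; ".join(
        f"{k}={_fmt(v)}" for k, v in summary.global_score_stats.items()
    )
    return f"""<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>Domiscore territory report</title>
<style>body{{font-family:sans-serif;margin:2em}}table{{border-collapse:collapse}}
td,th{{border:1px solid #ccc;padding:4px 10px}}</style></head>
<body>
<h1>Domiscore territory report</h1>
<p>grid {escape(summary.metadata.get('grid_version', '?'))} —
{summary.n_dwellings} dwellings — penalty mode
{escape(summary.metadata.get('penalty_mode', '?'))} —
{summary.alert_count} alerts</p>
<p>global score: {escape(stats)}</p>
<h2>Equivalence classes</h2>
<table><tr><th>green</th><th>yellow</th><th>orange</th><th>red</th></tr>
<tr>{classes}</tr></table>
<h2>Theme profile</h2>
<table><tr><th>theme</th>{''.join(f'<th>{c}</th>' for c in COLOR_BINS)}</tr>
{''.join(rows)}
</table>
</body></html>
"""
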