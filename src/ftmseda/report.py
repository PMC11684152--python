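"""Provenance report and export bundle.

The report is a self-contained HTML document rendered from an internal
markdown template: the uploaded-data summary, the upload selections, each
calculated property with its defining equation (plain text), every filter
with before/after peak counts, and the settings and label tallies of any
group comparisons.  Given identical provenance and a pinned timestamp the
report is byte-identical across runs.

The export bundle writes the processed data file and molecular
identification file (with calculated columns) back to CSV — separately and
optionally merged on the mass identifier — plus group-summary and
uniqueness-test CSVs when comparisons were run, and the report.
"""

from __future__ import annotations

import html as _html
import re
from pathlib import Path

import pandas as pd

from .compare import ComparisonResult, comparison_csv
from .dataset import FTMSDataset, ValidationError, write_generalized_output, _now

#: Plain-text equations shown in the report for each calculated column.
EQUATIONS = {
    "OtoC": "O:C = O / C",
    "HtoC": "H:C = H / C",
    "NtoC": "N:C = N / C",
    "PtoC": "P:C = P / C",
    "NtoP": "N:P = N / P (P >= 1)",
    "KendrickMass": "KM = mass * 14 / 14.01565",
    "KendrickDefect": "KMD = ceiling(KM) - KM",
    "NOSC": "NOSC = 4 - (4C + H - 3N - 2O - 2S + 5P) / C",
    "GFE": "GFE = 60.3 - 28.5 * NOSC  (kJ per mol C)",
    "AI": "AI = (1 + C - O - S - 0.5H) / (C - O - S - N - P), clamped to 0",
    "AImod": "AI_mod = AI with O replaced by 0.5 O",
    "DBE": "DBE = 1 + 0.5 * (2C - H + N + P)",
    "ElementalClass": "concatenation of element symbols present (C,H,N,O,S,P order)",
    "CompoundClass": "class of the (O:C, H:C) point in the boundary table",
}


def _md_to_html(md: str) -> str:
    """Tiny markdown renderer: headings, bullet lists, tables, paragraphs."""
    lines = md.splitlines()
    out: list[str] = []
    in_list = in_table = False
    for line in lines:
        if in_list and not line.startswith("- "):
            out.append("</ul>")
            in_list = False
        if in_table and not line.startswith("|"):
            out.append("</table>")
            in_table = False
        if m := re.match(r"^(#{1,4}) (.*)$", line):
            level = len(m.group(1))
            out.append(f"<h{level}>{_html.escape(m.group(2))}</h{level}>")
        elif line.startswith("- "):
            if not in_list:
                out.append("<ul>")
                in_list = True
            out.append(f"<li>{_html.escape(line[2:])}</li>")
        elif line.startswith("|"):
            cells = [c.strip() for c in line.strip("|").split("|")]
            if all(set(c) <= {"-", ":", " "} and c for c in cells):
                continue  # separator row
            tag = "th" if not in_table else "td"
            if not in_table:
                out.append("<table>")
                in_table = True
            out.append("<tr>" + "".join(f"<{tag}>{_html.escape(c)}</{tag}>"
                                        for c in cells) + "</tr>")
        elif line.strip():
            out.append(f"<p>{_html.escape(line)}</p>")
    if in_list:
        out.append("</ul>")
    if in_table:
        out.append("</table>")
    return "\n".join(out)


_STYLE = ("body{font-family:sans-serif;max-width:60em;margin:2em auto}"
          "table{border-collapse:collapse}"
          "td,th{border:1px solid #999;padding:0.3em 0.6em}")


def generate_report(ds: FTMSDataset,
                    comparisons: list[ComparisonResult] | None = None,
                    timestamp: str | None = None) -> str:
    """Render the analysis summary report as a self-contained HTML string.

    Pass a fixed ``timestamp`` for byte-identical output across runs.
    """
    if not ds.provenance:
        raise ValidationError("no provenance recorded; nothing to report")
    ts = timestamp if timestamp is not None else _now()
    md: list[str] = ["# FT-MS exploratory analysis report",
                     f"Generated: {ts}",
                     "## Data summary",
                     f"- Peaks: {ds.n_peaks}",
                     f"- Samples: {ds.n_samples}",
                     f"- Data scale: {ds.data_scale}",
                     f"- Missing-value code: {ds.missing_code}",
                     f"- Peaks with molecular formula: {int(ds.has_formula().sum())}"]

    upload = [s for s in ds.provenance if s.name == "upload"]
    if upload:
        md.append("## Upload selections")
        for k, v in upload[0].params.items():
            md.append(f"- {k}: {v}")

    calc_cols = [c for c in EQUATIONS if c in ds.mol_table.columns]
    if calc_cols:
        md.append("## Calculated properties")
        md.append("| property | equation |")
        md.append("|---|---|")
        for c in calc_cols:
            md.append(f"| {c} | {EQUATIONS[c]} |")

    md.append("## Processing steps")
    md.append("| step | parameters | peaks before | peaks after | samples after |")
    md.append("|---|---|---|---|---|")
    for step in ds.provenance:
        params = "; ".join(f"{k}={v}" for k, v in step.params.items()) or "-"
        md.append(f"| {step.name} | {params} | {step.n_peaks_before} "
                  f"| {step.n_peaks_after} | {step.n_samples_after} |")

    filters = [s for s in ds.provenance if s.name.startswith("filter")]
    if filters:
        md.append("## Filters")
        md.append("| filter | peaks before | peaks after |")
        md.append("|---|---|---|")
        for step in filters:
            md.append(f"| {step.name} | {step.n_peaks_before} | {step.n_peaks_after} |")

    for comp in comparisons or []:
        md.append(f"## Group comparison: {comp.group1} vs {comp.group2} ({comp.method})")
        cfg = comp.config
        md.append(f"- presence threshold: {cfg.pres_threshold}; "
                  f"absence threshold: {cfg.absn_threshold}; alpha: {cfg.alpha}")
        for label, count in sorted(comp.label_counts().items()):
            md.append(f"- {label}: {count}")

    body = _md_to_html("\n".join(md))
    return ("<!DOCTYPE html><html><head><meta charset='utf-8'>"
            f"<title>FT-MS analysis report</title><style>{_STYLE}</style></head>"
            f"<body>\n{body}\n</body></html>\n")


def export_bundle(ds: FTMSDataset, out_dir: str | Path,
                  comparisons: list[ComparisonResult] | None = None,
                  plots: list | None = None,
                  merged: bool = False,
                  mass_col: str = "Mass",
                  timestamp: str | None = None) -> dict[str, Path]:
    """Write the processed tables, optional merged sheet, comparison CSVs,
    plot tables, and the HTML report into ``out_dir``.

    Returns a name -> path map of everything written.  Re-importing the
    exported data/molecular files reproduces the dataset (observed values
    and formulas are lossless).
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as e:
        raise ValidationError(f"cannot create output directory {out_dir}: {e}") from e
    written: dict[str, Path] = {}
    data_path = out_dir / "processed_data.csv"
    mol_path = out_dir / "processed_molecular_identification.csv"
    write_generalized_output(ds, data_path, mol_path, mass_col=mass_col)
    written["data"] = data_path
    written["molecular"] = mol_path
    if merged:
        peaks = ds.peak_table.copy()
        if ds.missing_encoded:
            peaks = peaks.fillna(ds.missing_code)
        mol = ds.mol_table
        if mass_col in mol.columns:
            mol = mol.rename(columns={mass_col: f"{mass_col}_Da"})
        sheet = mol.join(peaks)
        merged_path = out_dir / "merged.csv"
        sheet.rename_axis(mass_col).reset_index().to_csv(merged_path, index=False)
        written["merged"] = merged_path
    for comp in comparisons or []:
        name = f"uniqueness_{comp.group1}_vs_{comp.group2}.csv"
        p = out_dir / name
        comparison_csv(comp).rename_axis(mass_col).reset_index().to_csv(p, index=False)
        written[name] = p
    for plot in plots or []:
        p = out_dir / f"plot_{plot.kind}.csv"
        plot.data.to_csv(p, index=False)
        written[f"plot_{plot.kind}"] = p
    report_path = out_dir / "report.html"
    report_path.write_text(generate_report(ds, comparisons, timestamp=timestamp))
    written["report"] = report_path
    return written
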