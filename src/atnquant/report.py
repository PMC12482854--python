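"""Human-readable report emission (plain text + HTML).

Every number shown here is read back from the CSV/JSON outputs of the run;
the report itself computes nothing.  Values are rounded to 4 decimals for
display; the CSVs keep full double precision.
"""

from __future__ import annotations

from pathlib import Path

from .staging import BiomarkerPanel


def _fmt(x) -> str:
    if x is None:
        return "n/a"
    return f"{x:.4f}"


def _rows(panel: BiomarkerPanel) -> list[tuple[str, str, str]]:
    t = panel.thresholds
    if panel.mode == "amypad":
        a_cut = f"CL<{t.cl_low:g} A- | {t.cl_low:g}-{t.cl_high:g} A_inter | >{t.cl_high:g} A+"
    else:
        a_cut = f"CL>={t.cl_binary:g} A+"
    return [
        ("Amyloid (A)", f"CL = {_fmt(panel.cl)}",
         f"{panel.a_status}   [{a_cut}]"),
        ("Tau (T2)", f"CTRz = {_fmt(panel.ctrz)}",
         f"{panel.t2_status}   [CTRz<{t.ctrz_cut:g} T2-]"),
        ("Neurodegeneration (N)", f"HAVAs = {_fmt(panel.havas)}",
         f"{panel.n_status}   [p>{t.havas_cut:g} N+]"),
    ]


def render_text(panel: BiomarkerPanel, provenance: dict | None = None) -> str:
    lines = ["A/T2/N quantification report", "=" * 28, ""]
    for axis, value, status in _rows(panel):
        lines.append(f"{axis:24s} {value:20s} {status}")
    lines += ["", f"A-status mode: {panel.mode}"]
    if panel.amyloid_tracer:
        lines.append(f"Amyloid tracer: {panel.amyloid_tracer}")
    if panel.tau_tracer:
        lines.append(f"Tau tracer: {panel.tau_tracer}")
    if panel.havas_model:
        lines.append(f"HAVAs model: {panel.havas_model}")
    for k, v in (provenance or {}).items():
        lines.append(f"{k}: {v}")
    return "\n".join(lines) + "\n"


def render_html(panel: BiomarkerPanel, provenance: dict | None = None) -> str:
    rows = "\n".join(
        f"<tr><td>{axis}</td><td>{value}</td><td>{status}</td></tr>"
        for axis, value, status in _rows(panel))
    prov = "\n".join(f"<li>{k}: {v}</li>"
                     for k, v in (provenance or {}).items())
    return f"""<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>A/T2/N report</title></head>
<body>
<h1>A/T2/N quantification report</h1>
<table border="1" cellpadding="4">
<tr><th>Axis</th><th>Value</th><th>Status</th></tr>
{rows}
</table>
<p>A-status mode: {panel.mode}</p>
<ul>{prov}</ul>
</body></html>
"""


def write_report(panel: BiomarkerPanel, outdir: str | Path,
                 provenance: dict | None = None) -> dict:
    outdir = Path(outdir)
    txt = outdir / "report.txt"
    html = outdir / "report.html"
    txt.write_text(render_text(panel, provenance))
    html.write_text(render_html(panel, provenance))
    return {"text": txt, "html": html}
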