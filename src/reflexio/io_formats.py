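"""Text I/O: unmerged reflection files, XML summaries, plot-data tables.

Two reflection dialects are supported: an XDS-ASCII-style format with
'!'-prefixed KEY=VALUE header lines, and a TSV fallback with '#'-prefixed
header lines.  Both round-trip bit-identically (values are written with
full repr precision).
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .reflection_model import ReflectionTable, UnitCell

__all__ = [
    "DatasetHeader",
    "FormatError",
    "read_reflections",
    "write_reflections",
    "write_xml_summary",
    "validate_summary",
    "write_increment_plot_data",
]


class FormatError(ValueError):
    pass


@dataclass(frozen=True)
class DatasetHeader:
    cell: UnitCell
    group_symbol: str
    oscillation_range: float = 1.0
    starting_angle: float = 0.0
    template_name: str = "frame_????.cbf"
    n_images: int = 1
    dataset_id: str = "ds0"

    def __post_init__(self) -> None:
        if self.oscillation_range <= 0:
            raise ValueError("oscillation_range must be > 0")
        if self.n_images < 1:
            raise ValueError("n_images must be >= 1")


_MANDATORY = ("UNIT_CELL_CONSTANTS", "SPACE_GROUP_SYMBOL", "OSCILLATION_RANGE",
              "STARTING_ANGLE", "NUMBER_OF_IMAGES")


def _fmt(x: float) -> str:
    return repr(float(x))


def _header_pairs(header: DatasetHeader) -> list[tuple[str, str]]:
    c = header.cell
    return [
        ("UNIT_CELL_CONSTANTS",
         " ".join(_fmt(v) for v in (c.a, c.b, c.c, c.alpha, c.beta, c.gamma))),
        ("SPACE_GROUP_SYMBOL", header.group_symbol),
        ("OSCILLATION_RANGE", _fmt(header.oscillation_range)),
        ("STARTING_ANGLE", _fmt(header.starting_angle)),
        ("NAME_TEMPLATE_OF_DATA_FRAMES", header.template_name),
        ("NUMBER_OF_IMAGES", str(header.n_images)),
        ("DATASET_ID", header.dataset_id),
    ]


def _header_from_pairs(kv: dict[str, str], path: str) -> DatasetHeader:
    for key in _MANDATORY:
        if key not in kv:
            raise FormatError(f"{path}: missing mandatory header field {key}")
    cell_vals = [float(x) for x in kv["UNIT_CELL_CONSTANTS"].split()]
    if len(cell_vals) != 6:
        raise FormatError(f"{path}: UNIT_CELL_CONSTANTS needs 6 numbers")
    return DatasetHeader(
        cell=UnitCell(*cell_vals),
        group_symbol=kv["SPACE_GROUP_SYMBOL"],
        oscillation_range=float(kv["OSCILLATION_RANGE"]),
        starting_angle=float(kv["STARTING_ANGLE"]),
        template_name=kv.get("NAME_TEMPLATE_OF_DATA_FRAMES", "frame_????.cbf"),
        n_images=int(kv["NUMBER_OF_IMAGES"]),
        dataset_id=kv.get("DATASET_ID", "ds0"),
    )


def read_reflections(
    path, dialect: str = "xds_ascii"
) -> tuple[DatasetHeader, ReflectionTable, int]:
    """Read a reflection file; returns (header, table, n_dropped).

    Rows with sigma <= 0 are dropped and counted in ``n_dropped``.
    Non-numeric data rows raise a :class:`FormatError` naming the line.
    """
    if dialect not in ("xds_ascii", "tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    marker = "!" if dialect == "xds_ascii" else "#"
    kv: dict[str, str] = {}
    rows: list[tuple] = []
    dataset_id = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(marker):
                body = line[1:].strip()
                if body in ("END_OF_DATA", "END_OF_HEADER"):
                    continue
                key, eq, value = body.partition("=")
                if eq:
                    kv[key.strip()] = value.strip()
                continue
            parts = line.split()
            if len(parts) != 6:
                raise FormatError(f"{path}:{lineno}: expected 6 columns")
            try:
                h, k, l = int(parts[0]), int(parts[1]), int(parts[2])
                i, s = float(parts[3]), float(parts[4])
                img = int(parts[5])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-numeric value") from None
            rows.append((h, k, l, i, s, img))
    header = _header_from_pairs(kv, str(path))
    df = pd.DataFrame(
        rows, columns=["h", "k", "l", "intensity", "sigma", "image"]
    )
    df["dataset_id"] = header.dataset_id
    keep = df["sigma"] > 0
    n_dropped = int((~keep).sum())
    table = ReflectionTable(df.loc[keep].reset_index(drop=True))
    return header, table, n_dropped


def write_reflections(
    header: DatasetHeader, table: ReflectionTable, path, dialect: str = "xds_ascii"
) -> None:
    """Write a reflection file; exact inverse of :func:`read_reflections`."""
    if dialect not in ("xds_ascii", "tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    marker = "!" if dialect == "xds_ascii" else "#"
    lines = [f"{marker}FORMAT=REFLEXIO_{dialect.upper()}"]
    for key, value in _header_pairs(header):
        lines.append(f"{marker}{key}= {value}")
    lines.append(f"{marker}END_OF_HEADER")
    df = table.df
    for h, k, l, i, s, img in zip(
        df["h"], df["k"], df["l"], df["intensity"], df["sigma"], df["image"]
    ):
        lines.append(f"{h} {k} {l} {_fmt(i)} {_fmt(s)} {img}")
    lines.append(f"{marker}END_OF_DATA")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# XML summary


def _shell_element(parent, shell) -> None:
    el = ET.SubElement(parent, "shell")
    for name in ("d_max", "d_min", "n_obs", "n_unique", "n_theoretical",
                 "completeness", "mean_i_over_sigma", "r_merge", "r_meas",
                 "multiplicity"):
        value = getattr(shell, name)
        child = ET.SubElement(el, name)
        child.text = "undefined" if value is None else repr(value)


def write_xml_summary(results: dict, path) -> None:
    """Serialize a pipeline results bundle to the summary XML layout.

    ``results`` must contain a ``branches`` list (one entry per Friedel
    setting) each with shells, overall stats, the resolution cutoff and the
    rejection count; optional ``grouped`` and ``sad_triage`` blocks are
    appended when present.  Raises :class:`FormatError` listing whatever is
    missing.
    """
    missing = _validate_results(results)
    if missing:
        raise FormatError(f"incomplete results; missing: {missing}")
    root = ET.Element("autoproc_summary")
    prog = ET.SubElement(root, "program")
    prog.text = "reflexio"
    for branch in results["branches"]:
        bel = ET.SubElement(root, "branch")
        bel.set("friedel_merged", "true" if branch["friedel_merged"] else "false")
        ET.SubElement(bel, "n_rejected").text = str(branch["n_rejected"])
        limit = ET.SubElement(bel, "resolution_limit")
        ET.SubElement(limit, "d_min").text = repr(branch["cutoff"].d_min_new)
        ET.SubElement(limit, "rule").text = branch["cutoff"].rule
        shells_el = ET.SubElement(bel, "shells")
        for shell in branch["shells"]:
            _shell_element(shells_el, shell)
        overall_el = ET.SubElement(bel, "overall")
        _shell_element(overall_el, branch["overall"])
    if "grouped" in results:
        g = results["grouped"]
        gel = ET.SubElement(root, "grouped")
        ET.SubElement(gel, "reference_id").text = g.reference_id
        ET.SubElement(gel, "group_symbol").text = g.group_symbol
        for ds, verdict in g.verdicts.items():
            v = ET.SubElement(gel, "sub_dataset")
            v.set("id", ds)
            v.set("verdict", verdict)
            if ds in g.operators:
                v.set("operator",
                      " ".join(str(x) for x in np.asarray(g.operators[ds]).flatten()))
        for inc in g.increments:
            iel = ET.SubElement(gel, "increment")
            iel.set("k", str(inc.k))
            iel.set("dataset_id", inc.dataset_id)
            _shell_element(iel, inc.overall)
    if "sad_triage" in results:
        s = results["sad_triage"]
        sel = ET.SubElement(root, "sad_triage")
        summary = s["summary"]
        ET.SubElement(sel, "trigger").text = "true" if summary.trigger else "false"
        ET.SubElement(sel, "threshold").text = repr(summary.threshold)
        for dmx, dmn, np_, v in zip(summary.d_max, summary.d_min,
                                    summary.n_pairs, summary.danom_over_sigma):
            shell = ET.SubElement(sel, "anom_shell")
            shell.set("d_max", repr(dmx))
            shell.set("d_min", repr(dmn))
            shell.set("n_pairs", str(np_))
            shell.set("danom_over_sigma", "undefined" if v is None else repr(v))
        plan = s.get("plan")
        if plan is not None:
            pel = ET.SubElement(sel, "trial_plan")
            ET.SubElement(pel, "estimated_mw").text = repr(plan.estimated_mw)
            for sf, hand in plan.trials:
                t = ET.SubElement(pel, "trial")
                t.set("solvent_fraction", repr(sf))
                t.set("hand", hand)
    ET.indent(root)
    ET.ElementTree(root).write(path, encoding="unicode", xml_declaration=True)


def _validate_results(results: dict) -> list[str]:
    missing = []
    branches = results.get("branches")
    if not branches:
        return ["branches"]
    for i, b in enumerate(branches):
        for key in ("friedel_merged", "n_rejected", "cutoff", "shells", "overall"):
            if key not in b:
                missing.append(f"branches[{i}].{key}")
    return missing


def load_summary_schema() -> dict:
    text = resources.files("reflexio.data").joinpath("summary_schema.json").read_text()
    return json.loads(text)


def validate_summary(path) -> list[str]:
    """Check a written summary against the bundled structural schema.

    Returns a list of problems (empty = valid).  This is a lightweight
    element-presence check, not full XSD validation.
    """
    schema = load_summary_schema()
    tree = ET.parse(path)
    root = tree.getroot()
    problems: list[str] = []

    def check(element, spec, where):
        for child_name, child_spec in spec.get("required_children", {}).items():
            found = element.findall(child_name)
            if child_spec.get("min", 1) > len(found):
                problems.append(f"{where}: missing <{child_name}>")
            for j, el in enumerate(found):
                check(el, child_spec, f"{where}/{child_name}[{j}]")
        for attr in spec.get("required_attributes", []):
            if attr not in element.attrib:
                problems.append(f"{where}: missing attribute {attr!r}")

    if root.tag != schema["root"]:
        problems.append(f"root tag {root.tag!r} != {schema['root']!r}")
    else:
        check(root, schema, schema["root"])
    return problems


def write_increment_plot_data(grouped, path) -> None:
    """One TSV row per (increment, shell): the Fig.-3-style bar-chart data."""
    if not grouped.increments:
        raise ValueError("grouped result has no increments")
    rows = []
    for inc in grouped.increments:
        for j, shell in enumerate(inc.shells):
            rows.append(
                {
                    "increment": inc.k,
                    "dataset_id": inc.dataset_id,
                    "shell": j,
                    "d_max": shell.d_max,
                    "d_min": shell.d_min,
                    "completeness": shell.completeness,
                    "mean_i_over_sigma": shell.mean_i_over_sigma,
                    "multiplicity": shell.multiplicity,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
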