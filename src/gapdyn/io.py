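"""Readers and writers for the package's text formats.

All artifacts are plain, diff-able delimited text: circuit parameter
files as key-value blocks with an explicit weight-matrix orientation
header; expression, maternal and trajectory tables as tab-separated
values with '#' comment headers carrying provenance (command line, seed,
package version).  Floats are serialised with ``repr`` so that
write-then-read is bit-exact.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from .circuit import GeneCircuit, StageSchedule
from .profiles import MaternalProfiles
from .synth import ExpressionDataset

__all__ = [
    "RunConfig",
    "read_circuit",
    "write_circuit",
    "read_expression_table",
    "write_expression_table",
    "read_maternal_table",
    "write_maternal_table",
    "write_trajectories",
]

ORIENTATION = "row=regulator col=target"
ORIENTATION_T = "row=target col=regulator"


class CircuitFormatError(ValueError):
    """Malformed circuit file; carries the offending line number."""

    def __init__(self, message, line=None):
        super().__init__(f"line {line}: {message}" if line else message)
        self.line = line


def _fmt(x: float) -> str:
    return repr(float(x))


def write_circuit(circuit: GeneCircuit, path, header_lines=()) -> None:
    """Serialise a circuit as a key-value block file (bit-exact floats)."""
    lines = ["# gapdyn circuit v1"]
    lines += [f"# {h}" for h in header_lines]
    lines.append(f"name {circuit.name}")
    lines.append("genes " + " ".join(circuit.genes))
    lines.append("maternal " + " ".join(circuit.maternal))
    lines.append(f"orientation {ORIENTATION}")
    for key, arr in (("R", circuit.production), ("lambda", circuit.decay),
                     ("h", circuit.basal)):
        lines.append(key + " " + " ".join(_fmt(v) for v in arr))
    lines.append("W")
    lines.append(". " + " ".join(circuit.genes))
    for b, reg in enumerate(circuit.genes):
        lines.append(reg + " " + " ".join(_fmt(v)
                                          for v in circuit.gap_weights[b]))
    lines.append("E")
    lines.append(". " + " ".join(circuit.genes))
    for m, reg in enumerate(circuit.maternal):
        lines.append(reg + " " + " ".join(_fmt(v)
                                          for v in circuit.maternal_weights[m]))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_circuit(path) -> GeneCircuit:
    """Parse a circuit file; raises :class:`CircuitFormatError` with the
    offending line number on malformed input.  The orientation header is
    mandatory; ``row=target col=regulator`` files are transposed on read.
    """
    with open(path) as fh:
        raw = fh.readlines()
    fields: dict = {}
    matrices: dict = {}
    transpose = None
    i = 0
    numbered = [(ln + 1, s.strip()) for ln, s in enumerate(raw)]
    lines = [(ln, s) for ln, s in numbered if s and not s.startswith("#")]
    while i < len(lines):
        ln, s = lines[i]
        tokens = s.split()
        key = tokens[0]
        if key in ("name",):
            fields["name"] = tokens[1] if len(tokens) > 1 else "circuit"
        elif key in ("genes", "maternal"):
            fields[key] = tuple(tokens[1:])
        elif key == "orientation":
            orient = " ".join(tokens[1:])
            if orient == ORIENTATION:
                transpose = False
            elif orient == ORIENTATION_T:
                transpose = True
            else:
                raise CircuitFormatError(f"unknown orientation {orient!r}", ln)
        elif key in ("R", "lambda", "h"):
            try:
                fields[key] = np.array([float(t) for t in tokens[1:]])
            except ValueError as exc:
                raise CircuitFormatError(f"bad number in {key} block: {exc}", ln)
        elif key in ("W", "E"):
            block = key
            if transpose is None:
                raise CircuitFormatError(
                    "orientation header must precede matrix blocks", ln)
            n_genes = len(fields.get("genes", ()))
            n_mat = len(fields.get("maternal", ()))
            if block == "W":
                expected, n_rows = n_genes, n_genes
                col_names = fields.get("genes", ())
            elif not transpose:
                expected, n_rows = n_genes, n_mat
                col_names = fields.get("genes", ())
            else:  # row=target: E rows are genes, columns maternal
                expected, n_rows = n_mat, n_genes
                col_names = fields.get("maternal", ())
            i += 1
            if i >= len(lines) or not lines[i][1].startswith("."):
                raise CircuitFormatError(f"{block} block missing its header "
                                         "row of column names", lines[i - 1][0])
            header = lines[i][1].split()[1:]
            if tuple(header) != col_names:
                raise CircuitFormatError(
                    f"{block} header names {header} do not match {col_names}",
                    lines[i][0])
            rows = []
            for r in range(n_rows):
                i += 1
                if i >= len(lines):
                    raise CircuitFormatError(f"{block} block truncated",
                                             lines[i - 1][0])
                ln_r, s_r = lines[i]
                toks = s_r.split()
                try:
                    row = [float(t) for t in toks[1:]]
                except ValueError as exc:
                    raise CircuitFormatError(f"bad number in {block}: {exc}", ln_r)
                if len(row) != expected:
                    raise CircuitFormatError(
                        f"{block} row {toks[0]!r} has {len(row)} entries, "
                        f"expected {expected}", ln_r)
                rows.append(row)
            matrices[block] = np.array(rows).reshape(n_rows, expected)
        else:
            raise CircuitFormatError(f"unknown key {key!r}", ln)
        i += 1
    if transpose is None:
        raise CircuitFormatError(
            "missing mandatory orientation header (expected 'orientation "
            f"{ORIENTATION}' or 'orientation {ORIENTATION_T}')")
    for req in ("genes", "maternal", "R", "lambda", "h"):
        if req not in fields:
            raise CircuitFormatError(f"missing block {req!r}")
    for req in ("W", "E"):
        if req not in matrices:
            raise CircuitFormatError(f"missing matrix block {req!r}")
    W, E = matrices["W"], matrices["E"]
    if transpose:
        W = W.T
        E = E.T  # file stored target-by-regulator
    try:
        return GeneCircuit(fields["genes"], fields["maternal"], fields["R"],
                           fields["lambda"], W, E, fields["h"],
                           name=fields.get("name", "circuit"))
    except ValueError as exc:
        raise CircuitFormatError(str(exc))


def _write_table(df: pd.DataFrame, path, header_lines=()):
    with open(path, "w") as fh:
        for h in header_lines:
            fh.write(f"# {h}\n")
        df.to_csv(fh, sep="\t", index=False)


def _read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#",
                       float_precision="round_trip")


def write_expression_table(ds: ExpressionDataset, path, header_lines=()) -> None:
    hdr = [f"provenance: {ds.provenance}"]
    if ds.seed is not None:
        hdr.append(f"seed: {ds.seed}")
    _write_table(ds.data, path, tuple(hdr) + tuple(header_lines))


def read_expression_table(path) -> ExpressionDataset:
    provenance, seed = "measured", None
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if body.startswith("provenance:"):
                provenance = body.split(":", 1)[1].strip()
            elif body.startswith("seed:"):
                seed = int(body.split(":", 1)[1])
    df = _read_table(path)
    return ExpressionDataset(df, provenance=provenance, seed=seed)


def write_maternal_table(profiles: MaternalProfiles, path, header_lines=()) -> None:
    _write_table(profiles.to_frame(), path, header_lines)


def read_maternal_table(path) -> MaternalProfiles:
    return MaternalProfiles.from_frame(_read_table(path))


def write_trajectories(trajs, schedule: StageSchedule, path,
                       header_lines=()) -> None:
    """Trajectory samples as a long table: position, time_min, time_class,
    gene, concentration."""
    bounds = schedule.class_bounds()
    labels = schedule.class_labels()

    def time_class(t):
        if t < schedule.c14a_start - 1e-9:
            return "C13M" if (schedule.c13_mitosis > 0
                              and t >= schedule.mitosis_start - 1e-9) else "C13"
        j = int(np.clip(np.searchsorted(bounds, t, side="right") - 1, 0,
                        len(labels) - 1))
        return labels[j]

    recs = []
    for tr in trajs:
        for k, t in enumerate(tr.times):
            for a, g in enumerate(tr.genes):
                recs.append((tr.position, t, time_class(t), g, tr.states[k, a]))
    df = pd.DataFrame(recs, columns=["position", "time_min", "time_class",
                                     "gene", "concentration"])
    _write_table(df, path, header_lines)


@dataclass
class RunConfig:
    """Run-wide configuration with documented defaults.

    Times are minutes, positions percent A-P, tolerances absolute unless
    stated.  ``sensitivity_threshold`` of ``None`` means 5% of the
    maximum observed d.
    """

    t0: float = 0.0                    # C13 onset
    c13_interphase: float = 16.0       # min
    c13_mitosis: float = 5.0           # min; division at its end
    c14a_duration: float = 50.0        # min, eight equal classes T1-T8
    n_classes: int = 8
    lattice_lo: float = 35.0           # trunk domain, % A-P
    lattice_hi: float = 75.0
    rtol: float = 1e-8                 # reference solver tolerances
    atol: float = 1e-10
    sensitivity_threshold: float | None = None
    seed: int = 0
    outdir: str = "."

    def schedule(self) -> StageSchedule:
        return StageSchedule(self.t0, self.c13_interphase, self.c13_mitosis,
                             self.c14a_duration, self.n_classes)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "RunConfig":
        if hasattr(source, "read"):
            payload = yaml.safe_load(source)
        else:
            try:
                with open(source) as fh:
                    payload = yaml.safe_load(fh)
            except (OSError, TypeError):
                payload = yaml.safe_load(source)
        return cls(**payload)
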