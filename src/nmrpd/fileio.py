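"""File formats: CIF, two-column patterns, restraint tables, build-up
curves and key-value config files."""

from __future__ import annotations

import logging
from pathlib import Path

import gemmi
import numpy as np

from .crystal import (
    AtomSite,
    CrystalStructure,
    UnitCell,
    space_group_from_symbol,
    space_group_from_triplets,
)
from .diffraction import CU_KA1, PowderPattern
from .fragments import perceive_bonds, _adjacency, _component
from .nmr import BuildupCurve, DistanceRestraint

log = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "read_cif",
    "write_cif",
    "read_pattern",
    "write_pattern",
    "read_restraints",
    "write_restraints",
    "read_buildup",
    "read_config",
]


class FormatError(ValueError):
    pass


_CELL_TAGS = ["_cell_length_a", "_cell_length_b", "_cell_length_c",
              "_cell_angle_alpha", "_cell_angle_beta", "_cell_angle_gamma"]
_SYMOP_TAGS = ["_space_group_symop_operation_xyz", "_symmetry_equiv_pos_as_xyz"]


def _num(text: str) -> float:
    """Parse a CIF number, dropping any '(esd)' suffix."""
    return float(text.split("(")[0])


def _assign_molecules(sites, cell):
    """Group asymmetric-unit atoms into molecules by bond connectivity;
    the largest component is 'cation', the smallest 'anion' (two-component
    salts), others get mol<N> labels."""
    cart = cell.orthogonalize(np.array([s.frac for s in sites], float))
    bonds = perceive_bonds([s.element for s in sites], cart)
    adj = _adjacency(len(sites), bonds)
    unassigned = set(range(len(sites)))
    comps = []
    while unassigned:
        start = min(unassigned)
        comp = _component(start, adj, (-1, -2))
        comps.append(sorted(comp))
        unassigned -= comp
    comps.sort(key=len, reverse=True)
    for ci, comp in enumerate(comps):
        if len(comps) == 2:
            name = "cation" if ci == 0 else "anion"
        else:
            name = f"mol{ci + 1}"
        for i in comp:
            sites[i].molecule_id = name
    return sites


def read_cif(path) -> CrystalStructure:
    """Read one structure from a CIF file (core dictionary tags)."""
    doc = gemmi.cif.read_file(str(path))
    block = doc.sole_block() if len(doc) == 1 else doc[0]

    cell_vals = []
    for tag in _CELL_TAGS:
        v = block.find_value(tag)
        if v is None:
            raise FormatError(f"missing {tag}")
        cell_vals.append(_num(v))
    cell = UnitCell(*cell_vals)

    triplets = None
    for tag in _SYMOP_TAGS:
        col = block.find_loop(tag)
        vals = [gemmi.cif.as_string(v) for v in col]
        if vals:
            triplets = vals
            break
    symbol = block.find_value("_symmetry_space_group_name_H-M") or \
        block.find_value("_space_group_name_H-M_alt") or "?"
    symbol = gemmi.cif.as_string(symbol) if symbol != "?" else "?"
    if triplets:
        sg = space_group_from_triplets(triplets, symbol=symbol)
    elif symbol != "?":
        sg = space_group_from_symbol(symbol)
    else:
        raise FormatError("missing _space_group_symop_operation_xyz "
                          "(or _symmetry_equiv_pos_as_xyz or a space-group symbol)")

    table = block.find("_atom_site_", ["label", "type_symbol", "fract_x",
                                       "fract_y", "fract_z"])
    if len(table) == 0:
        raise FormatError("missing _atom_site_label loop")
    occ_col = block.find_loop("_atom_site_occupancy")
    occs = [_num(gemmi.cif.as_string(v)) for v in occ_col] if occ_col else None
    sites = []
    for i, row in enumerate(table):
        sites.append(AtomSite(
            label=row[0],
            element=row[1],
            frac=(_num(row[2]), _num(row[3]), _num(row[4])),
            occupancy=occs[i] if occs else 1.0,
        ))
    _assign_molecules(sites, cell)
    mr = sum(gemmi.Element(s.element).weight * s.occupancy for s in sites)
    return CrystalStructure(cell=cell, space_group=sg, asym_sites=sites,
                            z=sg.n_operators, mr=mr)


def write_cif(structure: CrystalStructure, path, data_name="nmrpd") -> None:
    """Write a minimal core-CIF description of a structure."""
    c = structure.cell
    lines = [f"data_{data_name}"]
    lines += [
        f"_cell_length_a    {c.a:.6f}",
        f"_cell_length_b    {c.b:.6f}",
        f"_cell_length_c    {c.c:.6f}",
        f"_cell_angle_alpha {c.alpha:.4f}",
        f"_cell_angle_beta  {c.beta:.4f}",
        f"_cell_angle_gamma {c.gamma:.4f}",
        f"_symmetry_space_group_name_H-M '{structure.space_group.symbol}'",
        "loop_",
        "_space_group_symop_operation_xyz",
    ]
    lines += [f"  '{op.triplet()}'" for op in structure.space_group.operators]
    lines += [
        "loop_",
        "_atom_site_label",
        "_atom_site_type_symbol",
        "_atom_site_fract_x",
        "_atom_site_fract_y",
        "_atom_site_fract_z",
        "_atom_site_occupancy",
    ]
    for s in structure.asym_sites:
        x, y, z = s.frac
        lines.append(f"  {s.label} {s.element} {x:.6f} {y:.6f} {z:.6f} "
                     f"{s.occupancy:.4f}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_pattern(pattern: PowderPattern, path) -> None:
    """Two-column 2θ/intensity text with '#' metadata header lines."""
    lines = [f"# wavelength {pattern.wavelength:.6f}"]
    if pattern.fwhm is not None:
        lines.append(f"# fwhm {pattern.fwhm:.4f}")
    lines += [f"{t:.4f} {i:.6f}" for t, i in zip(pattern.two_theta, pattern.intensity)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_pattern(path) -> PowderPattern:
    """Read a two-column pattern; header lines are optional."""
    wavelength, fwhm = CU_KA1, None
    tts, ys = [], []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            parts = line[1:].split()
            if len(parts) >= 2 and parts[0] == "wavelength":
                wavelength = float(parts[1])
            elif len(parts) >= 2 and parts[0] == "fwhm":
                fwhm = float(parts[1])
            continue
        cols = line.split()
        if len(cols) < 2:
            raise FormatError(f"pattern line has fewer than two columns: {raw!r}")
        tts.append(float(cols[0]))
        ys.append(float(cols[1]))
    if not tts:
        raise FormatError(f"no data rows in pattern file {path}")
    return PowderPattern(np.array(tts), np.array(ys), wavelength, fwhm)


def write_restraints(restraints, path) -> None:
    lines = ["# selA selB d0 sigma delta rank"]
    for r in restraints:
        lines.append(f"{r.selection_a} {r.selection_b} {r.d0:.4f} "
                     f"{r.sigma:.4f} {r.delta:.4f} {r.rank}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_restraints(path):
    """Restraint table: one `selA selB d0 sigma delta rank` row per line."""
    out = []
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#")[0].strip()
        if not line:
            continue
        cols = line.split()
        if len(cols) != 6:
            raise FormatError(f"restraint line needs 6 fields: {raw!r}")
        out.append(DistanceRestraint(
            selection_a=cols[0], selection_b=cols[1], d0=float(cols[2]),
            sigma=float(cols[3]), delta=float(cols[4]), rank=int(cols[5]),
        ))
    return out


def read_buildup(path, kind="CP") -> BuildupCurve:
    """Two-column time (ms) / intensity text."""
    ts, ys = [], []
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#")[0].strip()
        if not line:
            continue
        cols = line.split()
        if len(cols) < 2:
            raise FormatError(f"build-up line has fewer than two columns: {raw!r}")
        ts.append(float(cols[0]))
        ys.append(float(cols[1]))
    return BuildupCurve(np.array(ts), np.array(ys), kind=kind)


def read_config(path) -> dict:
    """key = value (or key value) structured text; values auto-typed."""
    out = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#")[0].strip()
        if not line:
            continue
        if "=" in line:
            key, _, val = line.partition("=")
        else:
            key, _, val = line.partition(" ")
        key, val = key.strip(), val.strip()
        if not key or not val:
            raise FormatError(f"malformed config line: {raw!r}")
        for cast in (int, float):
            try:
                out[key] = cast(val)
                break
            except ValueError:
                continue
        else:
            out[key] = val
    return out
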