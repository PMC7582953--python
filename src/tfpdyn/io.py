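"""Readers and writers for the pipeline's file formats.

Canonical tabular dialect: UTF-8 TSV with a header row and '#' comment
lines. Structural ensembles are multi-model PDB (MODEL/ENDMDL) read and
written through gemmi with author residue numbering preserved (Met0 =
residue 0 accepted). FASTA goes through Biopython. A minimal read-only
NMR-STAR 3.1 reader maps deposited heteronuclear relaxation saveframes
(T1/T2/NOE loops) onto :class:`RelaxationDataset` for validation
against public BMRB entries.

Parsers reject malformed records with the offending line named; they
never silently coerce.
"""

from __future__ import annotations

import math
import re
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import gemmi
import numpy as np
import pandas as pd
from Bio import SeqIO

from .classify import RegionScheme
from .ensemble import BACKBONE_ATOMS, StructureEnsemble
from .fitting import FitResult, RelaxationDataset, RelaxationRecord

PathLike = Union[str, Path]

RELAXATION_COLUMNS = (
    "residue_id", "residue_name", "field_mhz",
    "r1", "r1_err", "r2", "r2_err", "noe", "noe_err", "flags",
)


def _opt_float(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str) and value.strip() in ("", ".", "NA", "nan"):
        return None
    return float(value)


def read_relaxation_tsv(path: PathLike, name: Optional[str] = None,
                        temperature_k: float = 310.15) -> RelaxationDataset:
    """Read a per-residue relaxation table.

    Required columns: residue_id, residue_name, field_mhz, r1, r1_err,
    r2, r2_err, noe, noe_err, flags (comma-separated labels; empty OK).
    Missing values may be blank or '.'.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in RELAXATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    records: List[RelaxationRecord] = []
    seen = {}
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        try:
            rid = int(row["residue_id"])
            fmhz = float(row["field_mhz"])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path} line {line}: unparseable residue_id/field_mhz") from exc
        key = (rid, fmhz)
        if key in seen:
            raise ValueError(
                f"{path} line {line}: duplicate record for residue {rid} at "
                f"{fmhz} MHz (first on line {seen[key]})"
            )
        seen[key] = line
        flags = frozenset(
            f.strip() for f in str(row["flags"] or "").split(",")
            if f.strip() and f.strip().lower() != "nan"
        )
        try:
            rec = RelaxationRecord(
                residue_id=rid,
                residue_name=str(row["residue_name"]),
                field_mhz=fmhz,
                r1=_opt_float(row["r1"]), r1_err=_opt_float(row["r1_err"]),
                r2=_opt_float(row["r2"]), r2_err=_opt_float(row["r2_err"]),
                noe=_opt_float(row["noe"]), noe_err=_opt_float(row["noe_err"]),
                flags=flags,
            )
        except ValueError as exc:
            raise ValueError(f"{path} line {line}: {exc}") from exc
        records.append(rec)
    return RelaxationDataset(
        name=name or path.stem, temperature_k=temperature_k, records=records
    )


def write_relaxation_tsv(dataset: RelaxationDataset, path: PathLike,
                         header_comment: str = "") -> None:
    rows = []
    for r in dataset.records:
        rows.append({
            "residue_id": r.residue_id, "residue_name": r.residue_name,
            "field_mhz": r.field_mhz,
            "r1": r.r1, "r1_err": r.r1_err, "r2": r.r2, "r2_err": r.r2_err,
            "noe": r.noe, "noe_err": r.noe_err,
            "flags": ",".join(sorted(r.flags)),
        })
    df = pd.DataFrame(rows, columns=list(RELAXATION_COLUMNS))
    with open(path, "w") as fh:
        if header_comment:
            for ln in header_comment.splitlines():
                fh.write(f"# {ln}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def write_fit_tsv(fit: FitResult, path: PathLike, header_comment: str = "") -> None:
    """Write per-residue model-free fit results as TSV."""
    rows = []
    for rid in sorted(fit.residues):
        rf = fit.residues[rid]
        p = rf.params
        rows.append({
            "residue_id": rid,
            "residue_name": rf.residue_name,
            "model": rf.model_id if p is not None else "",
            "s2": None if p is None else p.order_parameter,
            "s2_err": rf.param_errors.get("s2"),
            "tau_e_ps": None if p is None else p.tau_e_ps,
            "rex_s1": None if p is None else p.rex,
            "rex_field_mhz": None if p is None or p.rex is None else p.rex_field_mhz,
            "s2_f": None if p is None else p.s2_f,
            "s2_s": None if p is None else p.s2_s,
            "tau_s_ns": None if p is None else p.tau_s_ns,
            "chi2": rf.chi2,
            "dof": rf.dof,
            "satisfactory": rf.satisfactory,
            "skipped": rf.skipped or "",
        })
    df = pd.DataFrame(rows)
    with open(path, "w") as fh:
        if header_comment:
            for ln in header_comment.splitlines():
                fh.write(f"# {ln}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# PDB ensembles


def read_pdb_ensemble(path: PathLike, chain: Optional[str] = None,
                      name: Optional[str] = None) -> StructureEnsemble:
    """Read a multi-model PDB file into a backbone ensemble.

    First chain used unless ``chain`` names one; altlocs beyond the
    first are ignored; hydrogens are not needed. Residues missing any
    backbone atom (N, CA, C) in any model are dropped from all models so
    the composition invariant holds; author numbering is preserved.
    """
    path = Path(path)
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    if len(st) < 1:
        raise ValueError(f"{path}: no models")
    per_model: List[Dict[int, Dict[str, np.ndarray]]] = []
    res_names: Dict[int, str] = {}
    for model in st:
        chains = [c for c in model if chain is None or c.name == chain]
        if not chains:
            raise ValueError(f"{path}: chain {chain!r} not found")
        ch = chains[0]
        coords: Dict[int, Dict[str, np.ndarray]] = {}
        for res in ch:
            rid = res.seqid.num
            atoms = {}
            for at in res:
                if at.name in BACKBONE_ATOMS and at.name not in atoms:
                    atoms[at.name] = np.array([at.pos.x, at.pos.y, at.pos.z])
            if len(atoms) == 3:
                coords[rid] = atoms
                res_names.setdefault(rid, res.name)
        per_model.append(coords)
    common = sorted(set.intersection(*(set(m) for m in per_model)))
    if not common:
        raise ValueError(f"{path}: no residues with complete backbone in all models")
    n_models, n_res = len(per_model), len(common)
    out = np.empty((n_models, n_res, 3, 3))
    for mi, coords in enumerate(per_model):
        for ri, rid in enumerate(common):
            for ai, aname in enumerate(BACKBONE_ATOMS):
                out[mi, ri, ai] = coords[rid][aname]
    return StructureEnsemble(
        residue_ids=np.array(common),
        residue_names=[res_names[r] for r in common],
        coords=out,
        name=name or path.stem,
    )


def write_pdb_ensemble(ensemble: StructureEnsemble, path: PathLike) -> None:
    """Write the backbone ensemble as a multi-model PDB file."""
    st = gemmi.Structure()
    st.name = ensemble.name
    for mi in range(ensemble.n_models):
        model = gemmi.Model(mi + 1)
        ch = gemmi.Chain("A")
        for ri, rid in enumerate(ensemble.residue_ids):
            res = gemmi.Residue()
            res.name = (ensemble.residue_names[ri] or "GLY")[:3].upper().ljust(3)
            res.seqid = gemmi.SeqId(int(rid), " ")
            for ai, aname in enumerate(BACKBONE_ATOMS):
                at = gemmi.Atom()
                at.name = aname
                at.element = gemmi.Element("N" if aname == "N" else "C")
                x, y, z = ensemble.coords[mi, ri, ai]
                at.pos = gemmi.Position(float(x), float(y), float(z))
                res.add_atom(at)
            ch.add_residue(res)
        model.add_chain(ch)
        st.add_model(model)
    st.write_pdb(str(path))


def read_fasta(path: PathLike) -> Dict[str, str]:
    """Sequences keyed by record id."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# minimal NMR-STAR 3.1 heteronuclear relaxation reader


_STAR_FRAME_FIELDS = {
    "heteronucl_T1_relaxation": ("_T1.Seq_ID", "_T1.Val", "_T1.Val_err", "r1"),
    "heteronucl_T2_relaxation": ("_T2.Seq_ID", "_T2.Val", "_T2.Val_err", "r2"),
    "heteronucl_NOEs": ("_Heteronucl_NOE.Seq_ID", "_Heteronucl_NOE.Val",
                        "_Heteronucl_NOE.Val_err", "noe"),
}


def _star_loops(text: str):
    """Yield (tags, rows) for every loop_ block in a STAR file."""
    pos = 0
    while True:
        start = text.find("loop_", pos)
        if start < 0:
            return
        stop = text.find("stop_", start)
        if stop < 0:
            stop = len(text)
        body = text[start + 5: stop]
        tags: List[str] = []
        rows: List[List[str]] = []
        lines = body.splitlines()
        i = 0
        while i < len(lines) and (not lines[i].strip() or lines[i].strip().startswith("_")):
            if lines[i].strip().startswith("_"):
                tags.append(lines[i].strip())
            i += 1
        data_tokens: List[str] = []
        for ln in lines[i:]:
            ln = ln.strip()
            if not ln or ln.startswith("#"):
                continue
            data_tokens.extend(re.findall(r"'[^']*'|\"[^\"]*\"|\S+", ln))
        if tags and data_tokens:
            ncol = len(tags)
            if len(data_tokens) % ncol != 0:
                raise ValueError(
                    f"NMR-STAR loop starting with tag {tags[0]!r}: token count "
                    f"{len(data_tokens)} is not a multiple of {ncol} columns"
                )
            rows = [data_tokens[k: k + ncol] for k in range(0, len(data_tokens), ncol)]
        yield tags, rows
        pos = stop + 5


def read_nmrstar_relaxation(path: PathLike, name: Optional[str] = None,
                            temperature_k: float = 310.15) -> RelaxationDataset:
    """Map NMR-STAR 3.1 heteronuclear relaxation loops to a dataset.

    Supports T1/T2 loops tabulated either as rates (s^-1) or times (s;
    detected from the saveframe's Tau_value/coherence unit tag when
    present, otherwise values > 20 are assumed to be ms times). The
    spectrometer frequency is taken from the
    ``Spectrometer_frequency_1H`` tag of the enclosing saveframe.
    """
    text = Path(path).read_text()
    # Split into saveframes so each loop is paired with its frequency tag.
    frames = re.split(r"(?=save_)", text)
    records: Dict[tuple, dict] = {}
    for frame in frames:
        freq_match = re.search(r"Spectrometer_frequency_1H\s+(\S+)", frame)
        if freq_match is None:
            continue
        field_mhz = float(freq_match.group(1).strip("'\""))
        unit_match = re.search(r"\.\s*(?:Val_units|T[12]_val_units)\s+(\S+)", frame)
        units = unit_match.group(1).strip("'\"").lower() if unit_match else None
        for tags, rows in _star_loops(frame):
            tagset = {t.split(".")[-1] for t in tags}
            kind = None
            for key, (seq_tag, val_tag, err_tag, quantity) in _STAR_FRAME_FIELDS.items():
                base = val_tag.split(".")[0].lstrip("_")
                if any(t.startswith(f"_{base}.") for t in tags):
                    kind = (seq_tag, val_tag, err_tag, quantity)
                    break
            if kind is None:
                continue
            seq_tag, val_tag, err_tag, quantity = kind
            idx = {t: i for i, t in enumerate(tags)}

            def col(tag, row, default=None):
                i = idx.get(tag)
                return row[i] if i is not None else default

            comp_tag = val_tag.split(".")[0] + ".Comp_ID"
            for row in rows:
                seq = col(seq_tag, row)
                val = col(val_tag, row)
                err = col(err_tag, row)
                if seq in (None, ".", "?") or val in (None, ".", "?"):
                    continue
                rid = int(seq)
                v = float(val)
                e = float(err) if err not in (None, ".", "?") else abs(v) * 0.05
                if quantity in ("r1", "r2"):
                    if units in ("s", "sec", "second", "seconds"):
                        v, e = 1.0 / v, e / v**2
                    elif units in ("ms", "msec"):
                        v, e = 1000.0 / v, 1000.0 * e / v**2
                    elif units in ("s-1", "s^-1", "hz", "1/s"):
                        pass
                    elif v > 20.0:  # heuristically a time in ms
                        v, e = 1000.0 / v, 1000.0 * e / v**2
                key = (rid, field_mhz)
                rec = records.setdefault(
                    key, {"residue_name": str(col(comp_tag, row, "XXX"))}
                )
                rec[quantity] = v
                rec[f"{quantity}_err"] = e if e > 0 else abs(v) * 0.05
    if not records:
        raise ValueError(f"{path}: no heteronuclear relaxation loops found")
    out = [
        RelaxationRecord(residue_id=rid, field_mhz=fmhz, **data)
        for (rid, fmhz), data in sorted(records.items())
    ]
    return RelaxationDataset(
        name=name or Path(path).stem, temperature_k=temperature_k, records=out
    )


# ---------------------------------------------------------------------------
# region schemes


def read_region_scheme(path: PathLike) -> RegionScheme:
    """Region scheme from YAML: {name: ..., regions: {loop_I: [[7,20]], ...}}."""
    import yaml

    data = yaml.safe_load(Path(path).read_text())
    regions = {
        str(k): tuple(tuple(int(x) for x in rng) for rng in v)
        for k, v in data["regions"].items()
    }
    return RegionScheme(regions, name=str(data.get("name", Path(path).stem)))


def write_region_scheme(scheme: RegionScheme, path: PathLike) -> None:
    import yaml

    data = {
        "name": scheme.name,
        "regions": {k: [list(r) for r in v] for k, v in scheme.regions.items()},
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
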