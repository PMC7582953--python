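"""Validation against publicly deposited structures and relaxation data.

These helpers fetch deposited multi-model PDB ensembles and BMRB
NMR-STAR relaxation entries over the network and push them through the
package's ensemble-disorder and model-free pipelines. They exist for
cross-checking the implementation against published per-region numbers
and therefore require internet access; everything else in the package
runs fully offline on synthetic data.
"""

from __future__ import annotations

import urllib.request
from pathlib import Path
from typing import Dict, Optional

from .classify import RegionScheme
from .ensemble import StructureEnsemble
from .fitting import RelaxationDataset
from . import io as tio

PDB_URL = "https://files.rcsb.org/download/{pdb_id}.pdb"
BMRB_URL = "https://bmrb.io/ftp/pub/bmrb/entry_directories/bmr{entry}/bmr{entry}_3.str"


def slurp1_region_scheme() -> RegionScheme:
    """Cys-anchored loop boundaries for mature SLURP-1 (residues 1-81).

    Disulfide scaffold: Cys3-Cys28, Cys21-Cys51, Cys55-Cys71, Cys72-Cys77
    (plus the loop-I Cys6-Cys15). Loops are the stretches protruding
    between their anchoring cysteines: loop I 4-20, loop II 29-50,
    loop III 56-70; the head is everything else except the first
    residue. These are the package's own Cys-anchored estimates; any
    reported aggregate echoes the scheme used.
    """
    return RegionScheme(
        {
            "loop_I": ((4, 20),),
            "loop_II": ((29, 50),),
            "loop_III": ((56, 70),),
            "head": ((2, 3), (21, 28), (51, 55), (71, 81)),
        },
        name="slurp1_cys_anchored",
    )


def fetch_pdb_ensemble(
    pdb_id: str, cache_dir: Optional[Path] = None, timeout_s: float = 15.0
) -> StructureEnsemble:
    """Download a deposited NMR ensemble and parse its backbone."""
    cache_dir = Path(cache_dir) if cache_dir else Path(".cache")
    cache_dir.mkdir(parents=True, exist_ok=True)
    path = cache_dir / f"{pdb_id.upper()}.pdb"
    if not path.exists():
        with urllib.request.urlopen(
            PDB_URL.format(pdb_id=pdb_id.upper()), timeout=timeout_s
        ) as resp:
            path.write_bytes(resp.read())
    return tio.read_pdb_ensemble(path, name=pdb_id.upper())


def fetch_bmrb_relaxation(
    entry: int, cache_dir: Optional[Path] = None, timeout_s: float = 15.0,
    temperature_k: float = 310.15,
) -> RelaxationDataset:
    """Download a BMRB entry and parse its heteronuclear relaxation loops."""
    cache_dir = Path(cache_dir) if cache_dir else Path(".cache")
    cache_dir.mkdir(parents=True, exist_ok=True)
    path = cache_dir / f"bmr{entry}_3.str"
    if not path.exists():
        with urllib.request.urlopen(
            BMRB_URL.format(entry=entry), timeout=timeout_s
        ) as resp:
            path.write_bytes(resp.read())
    return tio.read_nmrstar_relaxation(
        path, name=f"bmr{entry}", temperature_k=temperature_k
    )
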