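"""Access to the genome-scale example models.

The E. coli model iJO1366 ships with cobrapy and is loaded straight from the
installed package data, so the flagship example works without a download.
The Synechocystis sp. PCC 6803 model iJN678 is not redistributed anywhere
locally; it is looked up in a user-supplied location and, as a last resort,
fetched from the BiGG model repository.
"""

from __future__ import annotations

import urllib.request
from importlib import resources
from pathlib import Path
from typing import Optional

from .model_io import MetabolicModel, ModelReadError, read_sbml

__all__ = [
    "load_ecoli_ijo1366",
    "load_synechocystis_ijn678",
    "ISOPRENOID_GENE_ALIASES",
]

BIGG_URL = "http://bigg.ucsd.edu/static/models/{model}.xml"

#: Common name -> iJO1366 locus tag for the E. coli isoprenoid (MEP) pathway
#: genes, the alias table for reading FPP overexpression reports.
ISOPRENOID_GENE_ALIASES = {
    "dxs": "b0420",
    "dxr": "b0173",
    "ispD": "b2747",
    "ispE": "b1208",
    "ispF": "b2746",
    "ispG": "b2515",
    "ispH": "b0029",
    "idi": "b2889",
    "ispA": "b0421",
}

def load_ecoli_ijo1366() -> MetabolicModel:
    """The E. coli iJO1366 reconstruction, from cobrapy's bundled data."""
    path = resources.files("cobra") / "data" / "iJO1366.xml.gz"
    with resources.as_file(path) as p:
        if not p.exists():  # pragma: no cover - depends on cobra packaging
            raise ModelReadError(
                "iJO1366.xml.gz not found in the installed cobra package data"
            )
        return read_sbml(p)


def load_synechocystis_ijn678(
    path: Optional[Path] = None, timeout: float = 15.0
) -> MetabolicModel:
    """The Synechocystis sp. PCC 6803 iJN678 reconstruction.

    Resolution order: an explicit ``path``, ``models/iJN678.xml`` relative to
    the working directory, then a download from the BiGG model repository.
    """
    candidates = [path] if path is not None else []
    candidates += [Path("models/iJN678.xml"), Path("scratch/iJN678.xml")]
    for cand in candidates:
        if cand is not None and Path(cand).exists():
            return read_sbml(cand)
    url = BIGG_URL.format(model="iJN678")
    try:
        with urllib.request.urlopen(url, timeout=timeout) as response:
            data = response.read()
    except Exception as exc:
        raise ModelReadError(
            "iJN678 is not available locally (looked in models/ and scratch/) "
            f"and could not be downloaded from {url}: {exc}"
        ) from exc
    target = Path("scratch")
    target.mkdir(exist_ok=True)
    out = target / "iJN678.xml"
    out.write_bytes(data)
    return read_sbml(out)
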