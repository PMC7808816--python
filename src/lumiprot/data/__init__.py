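"""Packaged, checksummed residue-attribute tables.

``ctd_groups.tsv``
    The 13 physicochemical attributes used by the CTD descriptors, each
    partitioning the 20 amino acids into three disjoint groups (seven
    hydrophobicity scales, normalized Van der Waals volume, polarity,
    polarizability, charge, secondary-structure propensity, solvent
    accessibility).

``pseaac_properties.tsv``
    Nine residue properties used by the type-II pseudo amino acid
    composition: hydrophobicity, hydrophilicity, side-chain mass, pK1
    (alpha-COOH), pK2 (alpha-NH3+), pI, rigidity, flexibility and
    irreplaceability.  Provenance of each scale is documented in
    docs/methods.md; values are z-standardized before use, so affine
    rescalings of a column are immaterial.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources

_PKG = resources.files(__name__)


def _read_checked(name: str) -> str:
    manifest = json.loads((_PKG / "checksums.json").read_text())
    text = (_PKG / name).read_text()
    digest = hashlib.sha256(text.encode()).hexdigest()
    expected = manifest["sha256"][name]
    if digest != expected:
        raise RuntimeError(
            f"packaged data file {name} is corrupted: "
            f"sha256 {digest} != expected {expected}"
        )
    return text


def read_ctd_groups_text() -> str:
    return _read_checked("ctd_groups.tsv")


def read_pseaac_properties_text() -> str:
    return _read_checked("pseaac_properties.tsv")
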