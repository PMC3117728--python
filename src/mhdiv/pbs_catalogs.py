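"""Human class II beta-1 peptide-binding-site catalogs.

Two published crystallography-based catalogs of peptide-contacting
residues of the human DR beta chain are shipped, keyed by the customary
beta-chain residue numbering of the mature beta-1 domain:

* ``"brown"`` — the original DR1 structure contact set.
* ``"reche"`` — the later consensus contact map over a large panel of
  peptide/MHC structures (default downstream).

Fish peptide-binding codons are inferred by homology: the query protein
is pairwise-aligned to the packaged human beta-1 reference and the
cataloged human positions are carried across the alignment.
"""

from __future__ import annotations

#: mature HLA-DRB1*01:01 beta-1 domain (residues 1-95)
HUMAN_BETA1_REFERENCE = (
    "GDTRPRFLWQLKFECHFFNGTERVRLLERCIYNQEESVRFDSDVGEYRAV"
    "TELGRPDAEYWNSQKDLLEQRRAAVDTYCRHNYGVGESFTVQRRV"
)

#: beta-chain residues contacting bound peptide, DR1 crystal structure
BROWN_PBS_POSITIONS: tuple[int, ...] = (
    9, 11, 13, 26, 28, 30, 32, 37, 38, 47, 56, 57, 60, 61, 65,
    67, 68, 70, 71, 74, 78, 81, 82, 85, 86, 89, 90,
)

#: beta-chain consensus peptide-contact residues over many structures
RECHE_PBS_POSITIONS: tuple[int, ...] = (
    9, 11, 13, 26, 28, 30, 38, 47, 56, 57, 60, 61, 64, 67, 70,
    71, 74, 77, 78, 81, 82, 85, 86, 89,
)

CATALOGS: dict[str, tuple[int, ...]] = {
    "brown": BROWN_PBS_POSITIONS,
    "reche": RECHE_PBS_POSITIONS,
}


def catalog_positions(name: str) -> tuple[int, ...]:
    try:
        return CATALOGS[name]
    except KeyError:
        raise KeyError(
            f"unknown PBS catalog {name!r}; choose from {sorted(CATALOGS)}"
        ) from None
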