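"""Controlled vocabulary of tracked metabolites.

Canonical short names, backbone carbon counts and rotational-symmetry flags
for every species handled by the topology presets, plus a synonym map so
that tables using full names (e.g. "fumarate") are accepted.  Only backbone
carbons are tracked; cofactor moieties (CoA, phosphate) carry no tracer
information here.
"""

from __future__ import annotations

INTERNAL_STANDARD = "scyllo-inositol"

#: canonical name -> (n_carbons, has 2-fold rotational carbon symmetry)
CANONICAL: dict[str, tuple[int, bool]] = {
    "GLC": (6, False),   # glucose
    "G6P": (6, False),
    "F6P": (6, False),
    "DHAP": (3, False),
    "GAP": (3, False),
    "3PGA": (3, False),
    "2PGA": (3, False),
    "PEP": (3, False),
    "PYR": (3, False),
    "G3P": (3, False),   # glycerol-3-phosphate
    "ACD": (2, False),   # acetaldehyde
    "ACA": (2, False),   # acetyl-CoA backbone
    "CIT": (6, False),
    "ICT": (6, False),   # isocitrate
    "AKG": (5, False),
    "SUC": (4, True),
    "FUM": (4, True),
    "MAL": (4, False),
    "OAA": (4, False),
    "ASP": (4, False),
    "GLU": (5, False),
    "6PGA": (6, False),  # 6-phosphogluconate
    "Ru5P": (5, False),
    "R5P": (5, False),
    "SH7P": (7, False),  # sedoheptulose-7-phosphate
}

SYNONYMS: dict[str, str] = {
    "glucose": "GLC",
    "glucose-6-phosphate": "G6P",
    "fructose-6-phosphate": "F6P",
    "dihydroxyacetone phosphate": "DHAP",
    "glyceraldehyde-3-phosphate": "GAP",
    "3-phosphoglycerate": "3PGA",
    "2-phosphoglycerate": "2PGA",
    "phosphoenolpyruvate": "PEP",
    "pyruvate": "PYR",
    "glycerol-3-phosphate": "G3P",
    "acetaldehyde": "ACD",
    "acetyl-coa": "ACA",
    "citrate": "CIT",
    "isocitrate": "ICT",
    "alpha-ketoglutarate": "AKG",
    "akg": "AKG",
    "succinate": "SUC",
    "fumarate": "FUM",
    "malate": "MAL",
    "oxaloacetate": "OAA",
    "aspartate": "ASP",
    "glutamate": "GLU",
    "6-phosphogluconate": "6PGA",
    "ribulose-5-phosphate": "Ru5P",
    "ru5p": "Ru5P",
    "ribose-5-phosphate": "R5P",
    "sedoheptulose-7-phosphate": "SH7P",
    "sh7p": "SH7P",
}


def canonical_name(name: str) -> str:
    """Map a metabolite name or synonym to its canonical short name.

    Unknown names are returned unchanged (tables may contain species the
    vocabulary does not track, e.g. the internal standard).
    """
    if name in CANONICAL:
        return name
    key = name.strip().lower()
    if key in SYNONYMS:
        return SYNONYMS[key]
    upper = name.strip().upper()
    if upper in CANONICAL:
        return upper
    return name
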