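"""Bundled reference data: published-style LUAD marker association tables.

Three marker-by-clinicopathology count tables from lung adenocarcinoma
cohorts, as printed in the clinical literature:

* ``aldh1a1_ihc`` — ALDH1A1 protein by immunohistochemistry, n = 95
  (43 low / 52 high);
* ``e2f1_ihc`` — E2F1 protein by immunohistochemistry, n = 95
  (46 low / 49 high);
* ``e2f1_elisa`` — serum E2F1 by ELISA, n = 100 (56 low / 44 high).

Each table maps a clinical parameter to a 2×2 count layout: rows are the
two clinical levels, columns the marker low/high groups.  These are the
canonical worked inputs for :mod:`stemscore.clinical_assoc`.
"""

from __future__ import annotations

from .clinical_assoc import ContingencyTable2x2

__all__ = ["luad_marker_tables"]

# (row1_label, row2_label, a, b, c, d): a/b = row1 low/high, c/d = row2 low/high
_TABLES: dict[str, dict[str, tuple[str, str, int, int, int, int]]] = {
    "aldh1a1_ihc": {
        "gender": ("Female", "Male", 18, 30, 25, 22),
        "age": ("<50", ">=50", 7, 3, 36, 49),
        "stage": ("I+II", "III+IV", 26, 19, 17, 33),
        "invasion": ("T1+T2", "T3+T4", 28, 22, 15, 30),
        "lymphatic_metastasis": ("negative", "positive", 26, 23, 17, 29),
        "distant_metastasis": ("M0", "M1", 27, 18, 16, 34),
    },
    "e2f1_ihc": {
        "gender": ("Female", "Male", 26, 22, 20, 27),
        "age": ("<50", ">=50", 6, 4, 40, 45),
        "stage": ("I+II", "III+IV", 27, 18, 19, 31),
        "invasion": ("T1+T2", "T3+T4", 29, 21, 17, 28),
        "lymphatic_metastasis": ("negative", "positive", 28, 21, 18, 28),
        "distant_metastasis": ("M0", "M1", 27, 18, 19, 31),
    },
    "e2f1_elisa": {
        "gender": ("Female", "Male", 27, 22, 29, 22),
        "age": ("<50", ">=50", 3, 4, 53, 40),
        "stage": ("I+II", "III+IV", 30, 14, 26, 30),
        "invasion": ("T1+T2", "T3+T4", 32, 21, 24, 23),
        "lymphatic_metastasis": ("negative", "positive", 28, 16, 28, 28),
        "distant_metastasis": ("M0", "M1", 36, 18, 20, 26),
    },
}


def luad_marker_tables() -> dict[str, dict[str, ContingencyTable2x2]]:
    """The bundled LUAD marker tables as :class:`ContingencyTable2x2` objects."""
    out: dict[str, dict[str, ContingencyTable2x2]] = {}
    for marker, params in _TABLES.items():
        out[marker] = {}
        for param, (r1, r2, a, b, c, d) in params.items():
            out[marker][param] = ContingencyTable2x2(
                a=a, b=b, c=c, d=d,
                row_labels=(r1, r2),
                col_labels=("low", "high"),
            )
    return out
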