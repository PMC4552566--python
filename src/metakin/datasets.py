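"""Published reference values from the exercise cohort this package models.

The reference study profiled 30 blood metabolites (11 acylcarnitines,
18 amino acids, glucose) in 47 subjects during a graded cycle-ergometry
test and published the maximum fold change of every metabolite together
with its FDR-adjusted Wilcoxon signed-rank P-value.  The printed table
ships here as a small reference dataset: it anchors transform
consistency checks (log2/−log10 round-trips) and gives the worked
examples realistic numbers.  All columns are the printed (rounded)
values, not recomputations.
"""

from __future__ import annotations

from io import StringIO

import pandas as pd

_BIOMARKER_TABLE_CSV = """\
metabolite,mfc,log2_mfc,p_adj,neglog10_p
Acetylcarnitine (C2),1.97,0.98,2.84e-13,12.55
Propionylcarnitine (C3),1.52,0.60,2.84e-13,12.55
Alanine,1.42,0.51,2.84e-13,12.55
Valerylcarnitine (C5),1.38,0.46,4.49e-09,8.35
Arginine,1.36,0.44,6.85e-06,5.16
Glucose,1.32,0.40,2.38e-08,7.62
Butyrylcarnitine (C4),1.27,0.35,4.31e-08,7.37
Methylmalonylcarnitine (C3-DC-M),1.26,0.33,6.93e-08,7.16
Hydroxyvalerylcarnitine (C5-OH),1.26,0.33,3.35e-05,4.48
Octadecadienylcarnitine (C18:2),1.21,0.28,1.05e-04,3.98
Ornithine,1.19,0.25,1.87e-05,4.73
Tryptophan,1.18,0.24,9.28e-03,2.03
Octadecanoylcarnitine (C18),1.17,0.23,1.97e-05,4.71
Methionine,1.16,0.21,9.81e-03,2.01
Histidine,1.14,0.18,1.72e-05,4.76
Phenylalanine,1.14,0.18,1.51e-06,5.82
Hexadecanoylcarnitine (C16),1.12,0.16,7.68e-03,2.11
Citrulline,1.12,0.16,9.91e-02,1.00
Glutamic_Acid,1.12,0.17,1.48e-09,8.83
Tyrosine,1.12,0.17,1.21e-07,6.92
Glycine,1.11,0.15,1.48e-09,8.83
Lysine,1.11,0.15,7.77e-03,2.11
Proline,1.11,0.16,2.09e-02,1.68
Serine,1.11,0.15,9.10e-03,2.04
Octadecenoylcarnitine (C18:1),1.10,0.14,1.04e-02,1.98
Threonine,1.09,0.12,2.25e-02,1.65
Valine,1.09,0.12,2.25e-02,1.65
xLeucine (Leucine + Isoleucine),1.09,0.12,1.08e-02,1.97
Carnitine (C0),0.92,-0.12,1.08e-02,1.97
Aspartic_Acid,0.88,-0.19,4.55e-01,0.34
"""

_CLUSTER_TABLE_CSV = """\
metabolite,cluster
Alanine,1
Arginine,1
Aspartic_Acid,2
Carnitine (C0),2
Octadecanoylcarnitine (C18),2
Octadecenoylcarnitine (C18:1),2
Hydroxyvalerylcarnitine (C5-OH),2
Citrulline,2
Histidine,2
Serine,2
Threonine,2
Valine,2
xLeucine (Leucine + Isoleucine),2
Hexadecanoylcarnitine (C16),3
Methylmalonylcarnitine (C3-DC-M),3
Glutamic_Acid,3
Glycine,3
Lysine,3
Methionine,3
Ornithine,3
Phenylalanine,3
Proline,3
Tryptophan,3
Tyrosine,3
Octadecadienylcarnitine (C18:2),4
Glucose,4
Acetylcarnitine (C2),5
Propionylcarnitine (C3),6
Butyrylcarnitine (C4),6
Valerylcarnitine (C5),7
"""


def reference_biomarker_table() -> pd.DataFrame:
    """The published 30-metabolite MFC/significance ranking (printed values)."""
    return pd.read_csv(StringIO(_BIOMARKER_TABLE_CSV))


def reference_cluster_table() -> pd.DataFrame:
    """The published cluster affiliations (7 clusters at cut height 35)."""
    return pd.read_csv(StringIO(_CLUSTER_TABLE_CSV))
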