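"""Bundled worked-example data.

Small reference matrices from a published colon-adenocarcinoma lncRNA
co-expression analysis: the Spearman correlation block retained at
threshold 0.9 (8 mRNAs x 6 lncRNAs) and the same block after fusion with
secondary-structure scores, plus the six-lncRNA risk-model coefficients
from the accompanying prognosis model.  Values are reproduced at the
6-decimal precision they were printed at.
"""

from __future__ import annotations

import io

import pandas as pd

_LNC_COLS = "CASC21\tFEZF1.AS1\tKIAA0125\tRP11.25K19.1\tMAGI2.AS3\tDLX6.AS1"

_SPEARMAN_TSV = f"""\
mrna\t{_LNC_COLS}
POU5F1B\t0.921046\t-0.272906\t-0.198371\t-0.335172\t-0.083741\t0.207652
DDR2\t-0.055541\t-0.145469\t0.295115\t0.056139\t0.901414\t-0.019750
FEZF1\t-0.214465\t0.905106\t0.078724\t0.249223\t-0.129703\t-0.090882
MZB1\t-0.156008\t0.047820\t0.901879\t0.169155\t0.262776\t-0.068253
TOX\t-0.398056\t0.234735\t0.209269\t0.915596\t0.112641\t0.030225
CACNA2D1\t0.014141\t-0.193714\t0.247710\t0.047105\t0.906147\t0.024552
FCRL5\t-0.167879\t0.054787\t0.917191\t0.154289\t0.363034\t-0.087492
DLX6\t0.219619\t-0.153076\t-0.088336\t-0.009765\t-0.046828\t0.905186
"""

_ADJUSTED_TSV = f"""\
mrna\t{_LNC_COLS}
POU5F1B\t0.921046\t-0.382356\t-0.411440\t-0.335172\t-0.304581\t0.296538
DDR2\t-0.366222\t-0.561156\t0.613738\t0.427867\t0.901414\t-0.261861
FEZF1\t-0.656697\t1.000000\t0.819006\t0.626732\t-0.598957\t-0.365746
MZB1\t-0.769841\t0.847173\t0.952822\t0.716688\t0.719770\t-0.398660
TOX\t-0.398056\t0.234735\t0.209269\t0.915596\t0.112640\t0.074103
CACNA2D1\t0.160565\t-0.354152\t0.368323\t0.246121\t0.906147\t0.164745
FCRL5\t-0.474429\t0.557145\t0.917191\t0.479419\t0.466437\t-0.362183
DLX6\t0.381330\t-0.574835\t-0.615991\t-0.441327\t-0.387686\t0.905186
"""

#: Six-lncRNA colon-cancer risk model: multivariate Cox coefficients
#: (log-hazard per expression unit), keyed by Ensembl gene id.
SIGNATURE_COEFFICIENTS: dict[str, float] = {
    "ENSG00000259347.4": 0.0126948,   # RP11-798K3.2
    "ENSG00000228437.4": 0.0011064,   # RP11-400N13.2
    "ENSG00000253405.1": 0.0018182,   # EVX1-AS
    "ENSG00000271797.1": -0.0342018,  # CTC-428G20.6
    "ENSG00000166770.9": 0.0061149,   # ZNF667-AS1
    "ENSG00000264016.2": -0.0299009,  # CTC-297N7.9
}


def _parse(tsv: str) -> pd.DataFrame:
    df = pd.read_csv(io.StringIO(tsv), sep="\t", index_col=0)
    df.index.name = None
    return df


def load_example_correlation() -> pd.DataFrame:
    """Spearman correlation block C_ML retained at alpha = 0.9 (8 x 6)."""
    return _parse(_SPEARMAN_TSV)


def load_example_adjusted() -> pd.DataFrame:
    """The same block after secondary-structure fusion, AC_ML (8 x 6)."""
    return _parse(_ADJUSTED_TSV)
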