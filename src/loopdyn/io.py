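"""Tab-separated table readers/writers with provenance headers.

All tables are TSV with '#'-prefixed header metadata lines; the generators
and pipeline stages round-trip through these functions, so generated
datasets are readable by the stage readers without special-casing.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

RELAXATION_COLUMNS = ["residue", "field", "temperature",
                      "T1", "T1_err", "T2", "T2_err", "NOE", "NOE_err"]
DISPERSION_COLUMNS = ["residue", "field", "temperature", "nu_cpmg",
                      "R2eff", "R2eff_err", "T_rel"]
RDC_COLUMNS = ["residue", "D_obs"]


def write_table(df: pd.DataFrame, path: str | Path, provenance: str = "") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if provenance:
            fh.write(f"# loopdyn {provenance}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_table(path: str | Path, required: list[str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing required columns {missing}")
    return df


def read_relaxation(path: str | Path) -> pd.DataFrame:
    return read_table(path, required=[c for c in RELAXATION_COLUMNS
                                      if c != "temperature"])


def read_dispersion(path: str | Path) -> pd.DataFrame:
    return read_table(path, required=DISPERSION_COLUMNS)


def read_rdc(path: str | Path) -> pd.DataFrame:
    return read_table(path, required=RDC_COLUMNS)


def write_fasta(alignment, path: str | Path) -> None:
    from Bio import AlignIO
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    AlignIO.write(alignment, str(path), "fasta")
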