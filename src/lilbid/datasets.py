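"""Packaged reference tables for the dsDNA benchmark set.

Two read-only CSVs ship with the package:

* ``oligo_masses.csv`` — the 12 short oligonucleotides, the three 35mer
  scaffolds, their sequences and monoisotopic-rounded masses in Da;
* ``affinity_reference.csv`` — per duplex: GC content, theoretical and
  UV-measured melting temperature (mean ± s.e.m., replicate count), ITC
  dissociation constant in nM (mean ± s.e.m., replicate count; missing
  for the two binders beyond the ITC range), and the LILBID % ssDNA at
  1.1 mm (mean ± s.e.m. over five dissociation curves), plus each
  sample's role: nine ``model`` duplexes train the calibration lines and
  three ``test`` duplexes evaluate them.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .models import AffinityDatum, log10_kd_molar, sd_from_sem


def _read(name: str) -> pd.DataFrame:
    with resources.files("lilbid.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def oligo_masses() -> pd.DataFrame:
    """Oligonucleotide sequences and masses (Da), indexed by oligo name."""
    return _read("oligo_masses.csv").set_index("oligo")


def affinity_reference() -> pd.DataFrame:
    """Solution-state and LILBID reference values per duplex sample."""
    return _read("affinity_reference.csv").set_index("sample")


def duplex_mass(sample: str) -> float:
    """Mass of a duplex = shorter strand + its 35mer scaffold."""
    masses = oligo_masses()["mass_da"]
    scaffold = affinity_reference().loc[sample, "scaffold"]
    return float(masses[sample] + masses[scaffold])


def tm_training_data() -> list[AffinityDatum]:
    """The nine model duplexes: x = % ssDNA at 1.1 mm, y = UV T_m, with
    s.d. reconstructed from the printed s.e.m. and replicate counts."""
    ref = affinity_reference()
    out = []
    for sample, row in ref[ref["role"] == "model"].iterrows():
        out.append(
            AffinityDatum(
                sample=sample,
                x=row["pct_ss_1p1mm"],
                sx=sd_from_sem(row["pct_ss_sem"], int(row["n_lilbid"])),
                y=row["uv_tm_c"],
                sy=sd_from_sem(row["uv_tm_sem_c"], int(row["n_uv"])),
            )
        )
    return out


def kd_training_data() -> list[AffinityDatum]:
    """The seven model duplexes with ITC values: y = log10 K_d (molar),
    with the s.d. propagated from the nM scale by the delta method."""
    ref = affinity_reference()
    rows = ref[(ref["role"] == "model") & ref["itc_kd_nm"].notna()]
    out = []
    for sample, row in rows.iterrows():
        y, sy = log10_kd_molar(
            row["itc_kd_nm"], sd_from_sem(row["itc_kd_sem_nm"], int(row["n_itc"]))
        )
        out.append(
            AffinityDatum(
                sample=sample,
                x=row["pct_ss_1p1mm"],
                sx=sd_from_sem(row["pct_ss_sem"], int(row["n_lilbid"])),
                y=y,
                sy=sy,
            )
        )
    return out


def test_samples() -> pd.DataFrame:
    """The three held-out duplexes with their measured references and the
    % ssDNA means the models are evaluated at."""
    ref = affinity_reference()
    out = ref[ref["role"] == "test"].copy()
    out["log_kd_measured"] = [
        log10_kd_molar(v) if np.isfinite(v) else np.nan for v in out["itc_kd_nm"]
    ]
    return out
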