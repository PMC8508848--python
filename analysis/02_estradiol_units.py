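#!/usr/bin/env python
"""Check the aqueous-humor estradiol concentration table for unit
consistency: every pg/mL mean and SD should reproduce the printed nM
column at 272.38 g/mol and 2-decimal half-up rounding."""

from pathlib import Path

import pandas as pd

from iopgenes import assays, tables_io

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    rows = []
    for rec in tables_io.load_fixture("table9"):
        nm = assays.round_display(assays.pg_per_ml_to_nm(rec.value_pg_per_ml))
        nm_sd = assays.round_display(assays.pg_per_ml_to_nm(rec.sd_pg_per_ml))
        rows.append(
            {
                "label": rec.label,
                "n": rec.n,
                "pg_per_ml": rec.value_pg_per_ml,
                "pg_per_ml_sd": rec.sd_pg_per_ml,
                "computed_nm": nm,
                "printed_nm": rec.value_nm,
                "computed_nm_sd": nm_sd,
                "printed_nm_sd": rec.sd_nm,
                "consistent": nm == rec.value_nm and nm_sd == rec.sd_nm,
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "estradiol_units.tsv", sep="\t", index=False)
    print(df.to_string(index=False))
    print("all rows consistent:", bool(df["consistent"].all()))


if __name__ == "__main__":
    main()
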