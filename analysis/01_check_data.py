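#!/usr/bin/env python
"""Validate the bundled study data before any modelling.

Cross-checks every measured kinase IC50 against the pIC50 printed in the
descriptor table (they must agree at 3 decimals after the -log10
conversion), and records the shape of each fixture. Writes
results/data_checks.json.
"""

import json
from pathlib import Path

import qsarforge as qf

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    table = qf.load_descriptor_table()
    potencies = qf.load_kinase_potencies()
    panel = qf.load_kinase_panel()
    cells = qf.load_cell_potencies()

    discrepancies = qf.check_fixture_consistency(potencies, table)
    summary = {
        "descriptor_table": {
            "compounds": table.n_compounds,
            "descriptors": table.descriptor_names,
            "responses": {c: int(table.responses[c].notna().sum())
                          for c in table.response_names},
        },
        "kinase_potencies": len(potencies),
        "panel_kinases": len(panel),
        "cell_lines": sorted(cells.cell_line.unique().tolist()),
        "potency_pic50_discrepancies": discrepancies,
    }

    OUT.mkdir(exist_ok=True)
    (OUT / "data_checks.json").write_text(json.dumps(summary, indent=1))

    print(f"{table.n_compounds} compounds, {len(table.descriptor_names)} descriptors; "
          f"responses: {summary['descriptor_table']['responses']}")
    if discrepancies:
        raise SystemExit(f"FIXTURE MISMATCH: {discrepancies}")
    n_checked = sum(1 for r in potencies if r.target in ("RAF1", "V600E-B-RAF")
                    and r.compound_id in table.compound_ids)
    print(f"all {n_checked} IC50s shared with the descriptor table reproduce "
          f"their printed pIC50 at 3 decimals")
    print(f"wrote {OUT / 'data_checks.json'}")


if __name__ == "__main__":
    main()
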