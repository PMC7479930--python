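"""Load a flat file and check its long-format structure.

Writes a tiny benefits extract to a temp file, loads it with a declared
schema, and prints the structure report: duplicate (id, month) pairs and
within-unit gaps are quality signals, not load errors.
"""

import tempfile
from pathlib import Path

from adminqc import check_panel_structure, load_panel

CSV = """id,month,benefit
123-45-6789,2011-01,350
123-45-6789,2011-02,350
123-45-6789,2011-02,350
123-45-6789,2011-04,-9
987-65-4321,2011-01,510
"""

CONFIG = {
    "id_var": "id",
    "time_var": "month",
    "variables": [{"name": "benefit", "role": "numeric", "missing_codes": [-9]}],
}

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "extract.csv"
    path.write_text(CSV)
    panel = load_panel(path, CONFIG)
    report = check_panel_structure(panel)

print(report.to_frame().to_string(index=False))
print()
print(
    "The duplicated 2011-02 row and the gap at 2011-03 show up as one "
    "duplicate pair and one gap period; the -9 sentinel became a missing value."
)
print("missing benefit cells:", int(panel.records["benefit"].isna().sum()))
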