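"""Regenerate the packaged NtC class table (src/ntckit/data/ntc_classes.csv).

The table is deterministic (no seed); see ntckit.fixtures.make_reference_table.
"""

from pathlib import Path

from ntckit.fixtures import make_reference_table, write_table_csv

if __name__ == "__main__":
    out = Path(__file__).resolve().parent.parent / "src" / "ntckit" / "data" / "ntc_classes.csv"
    rows = make_reference_table()
    write_table_csv(rows, out)
    print(f"wrote {out}: {len(rows)} classes, {len({r['cana'] for r in rows})} CANA codes")
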