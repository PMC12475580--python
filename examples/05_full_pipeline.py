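"""Run all four stages end to end on a generated fixture set.

Equivalent to:
    conservemap make-fixtures --out fx --seed 3
    conservemap run --query fx/query.fasta --db-root fx/db_root \
        --struct-db fx/structures/struct_db.fasta --run-name demo
"""

import tempfile
from pathlib import Path

from conservemap import FilterSettings, RunConfig, load_query, run_pipeline
from conservemap.fixtures import write_fixture_set

with tempfile.TemporaryDirectory() as tmp:
    paths = write_fixture_set(Path(tmp) / "fx", seed=3)
    config = RunConfig(
        query=load_query(paths["query"]),
        db_root=paths["db_root"],
        run_name="demo",
        filters=FilterSettings(50.0, 100.0, 20.0),
        struct_db=paths["struct_db"],
        out_root=Path(tmp) / "outputs",
    )
    out_dir = run_pipeline(config)

    print("output directory:")
    for p in sorted(out_dir.iterdir()):
        print(f"  {p.name}  ({p.stat().st_size} bytes)")
    text = (out_dir / "demo_alignment.txt").read_text()
    print("\nfooter (run settings + accessions):")
    print(text[text.index("RUN SETTINGS") :])
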