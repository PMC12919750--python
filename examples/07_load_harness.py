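"""Concurrent-load harness over the in-process recommendation path.

Builds the database and a quickly-trained model, then issues simulated kiosk
sessions (profile -> triage prediction -> plan composition) from 5, 10, 20
and 50 concurrent threads, reporting mean latency and its SD per level.
Absolute timings are machine-dependent.
"""

import dataclasses
import tempfile
from importlib import resources
from pathlib import Path

from nutrikiosk.cohort import CohortConfig, generate_cohort
from nutrikiosk.evaluation import load_test
from nutrikiosk.food_db import init_db, load_foods_csv
from nutrikiosk.recommender import MLPSpec, save_model, train
from nutrikiosk.session_load import make_request_fn

with tempfile.TemporaryDirectory() as tmp:
    db_path = Path(tmp) / "kiosk.db"
    items, _ = load_foods_csv(str(resources.files("nutrikiosk") / "data" / "foods.csv"))
    init_db(items, path=db_path).close()

    records, _ = generate_cohort(dataclasses.replace(CohortConfig(seed=1), n_target=800))
    model = train(MLPSpec(seed=1, max_epochs=10), records)
    save_model(model, Path(tmp) / "model")

    request = make_request_fn(str(db_path), str(Path(tmp) / "model"))
    results = load_test(request, concurrency_levels=(5, 10, 20, 50),
                        requests_per_level=10, seed=1)
    print("concurrency   mean (s)   SD (s)   failures")
    for r in results:
        print(f"{r.concurrency:>11}   {r.mean_s:8.3f}   {r.sd_s:6.3f}   {r.failures:8d}")
    print("\nLatencies are wall-clock per request on this machine; the harness")
    print("verifies stability under load, not absolute speed.")
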