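"""Simulate the three encoding protocols (VR, RW, SL).

Generates the full synthetic study at the default study conditions — 20
participants per protocol, 60 encoded objects each, protocol-specific
encoding/retention envelopes — and writes the trial tables (plus the
generator's latent truth tables) under ``results/data/<PROTOCOL>/``.

Run from the repository root:  ``python analysis/01_simulate.py [seed]``
"""

import json
import sys
from pathlib import Path

from epimem import io, synth

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 2026
OUT = Path("results/data")


def main() -> None:
    io.setup_logging(OUT / "run.log")
    study = synth.simulate_study(seed=SEED)
    for proto, data in study.items():
        config = data["config"]
        meta = {"config_hash": io.config_hash(config), "seed": SEED}
        pdir = OUT / proto
        io.write_trials(data["encoding"], pdir / "encoding.csv", "encoding", meta)
        io.write_trials(data["source"], pdir / "source_trials.csv", "source", meta)
        io.write_trials(data["order"], pdir / "order_trials.csv", "order", meta)
        for name in ("sessions", "truth_source", "truth_order"):
            (pdir / f"{name}.csv").write_text(
                "# " + " ".join(f"{k}={v}" for k, v in sorted(meta.items())) + "\n"
                + data[name].to_csv(index=False)
            )
        (pdir / "config.json").write_text(json.dumps(config.to_dict(), indent=2))
        sess = data["sessions"]
        print(
            f"{proto}: {config.n_participants} participants, "
            f"encoding span {sess['encoding_span'].min()/60:.1f}-{sess['encoding_span'].max()/60:.1f} min, "
            f"retention {sess['retention'].min()/3600:.2f}-{sess['retention'].max()/3600:.2f} h"
        )
    print(f"data -> {OUT}")


if __name__ == "__main__":
    main()
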