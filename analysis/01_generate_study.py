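#!/usr/bin/env python
"""Materialise a complete synthetic study as CSV fixtures.

Generates the calibration series, pH screen, four kinetic time courses
(Ci = 25-100 mg/L, daily sampling over 96 h) and three isotherms
(30/40/50 C) from a single seed, writing the same CSV dialects the
analysis stages read. Downstream drivers (02-04) consume these files.
"""

from pathlib import Path

from biosorb.pipeline import load_config, write_fixtures

SEED = 20200107
OUT = Path(__file__).resolve().parents[1] / "results" / "synthetic_study"


def main():
    cfg = load_config(None, seed=SEED)
    paths = write_fixtures(cfg, OUT)
    print(f"synthetic study (seed {SEED}) written to {OUT}:")
    for name, p in sorted(paths.items()):
        print(f"  {name}: {p.name}")


if __name__ == "__main__":
    main()
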