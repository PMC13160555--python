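#!/usr/bin/env python
"""Parameter-recovery analysis, homoscedastic and heteroscedastic.

Simulates 30 fresh subjects on the full design, adds Gaussian noise at
sigma in {0.01, 0.05, 0.1, 0.2, 0.3}, refits, and reports the pooled
truth-vs-estimate Pearson r per family and noise level; then repeats
with the probability-binned SD profile rescaled to each level. Writes
results/recovery_report.json.
"""

import json
from pathlib import Path

from regimeshift import PopulationSpec, parameter_recovery

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 0


def main() -> None:
    spec = PopulationSpec(n_subjects=30)
    hom = parameter_recovery(spec, seed=SEED)
    het = parameter_recovery(spec, seed=SEED, heteroscedastic=True)
    report = {"homoscedastic": hom.to_dict(), "heteroscedastic": het.to_dict()}
    RESULTS.mkdir(exist_ok=True)
    (RESULTS / "recovery_report.json").write_text(json.dumps(report, indent=2))

    for name, rep in (("homoscedastic", hom), ("heteroscedastic", het)):
        print(f"{name} recovery:")
        for s in rep.noise_levels:
            print(f"  sigma={s:<5} r_alpha={rep.r_alpha[s]:.4f} "
                  f"r_beta={rep.r_beta[s]:.4f}")
        print(f"  min over levels: r_alpha={rep.min_r_alpha:.4f} "
              f"r_beta={rep.min_r_beta:.4f}")
    print(f"wrote {RESULTS}/recovery_report.json")


if __name__ == "__main__":
    main()
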