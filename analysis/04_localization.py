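#!/usr/bin/env python
"""Element-level localization of true enrichment.

Simulates genuine ChIP enrichment (8-fold, 50,000 reads/role) targeting
each of the three promoters in turn and checks that the screen's top
emergent peak is assigned to the targeted element — the synthetic analogue
of recovering a TRF2-like factor at the TATA-less H1 promoter and
Hox-like factors at the H3/H4 promoter.

Writes results/localization.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from hlbscreen.recovery import PipelineContext, reference_config, run_pipeline
from hlbscreen.simulate import SimMode

ROOT = Path(__file__).resolve().parent.parent
TARGETS = ["H1_promoter", "H3_H4_promoter", "H2A_H2B_promoter"]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=11)
    args = ap.parse_args()

    ctx = PipelineContext.build(seed=0)
    rows = []
    for target in TARGETS:
        call = run_pipeline(
            ctx,
            reference_config(SimMode.TRUE_PROMOTER, seed=args.seed, target_element=target),
        )
        top_elements = []
        if call.emergent_peaks:
            top = max(range(len(call.emergent_peaks)),
                      key=lambda i: call.emergent_peaks[i].max_ratio)
            top_elements = call.localization[top]
        rows.append(
            {
                "target": target,
                "label": call.label,
                "top_peak_elements": ",".join(top_elements),
                "correct": bool(top_elements and top_elements[0] == target),
            }
        )
    df = pd.DataFrame(rows)
    out = ROOT / "results" / "localization.tsv"
    out.parent.mkdir(exist_ok=True)
    df.to_csv(out, sep="\t", index=False)
    print(df.to_string(index=False))
    print(f"table: {out}")


if __name__ == "__main__":
    main()
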