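#!/usr/bin/env python
"""Score and rank the PD-L1 surface hydration sites.

Applies the per-site thermodynamic scoring (Etot, TStot, dH, dG, Kss) to the
packaged 28-site solvent-mapping table for apo PD-L1, classifies each site as
displaceable ("unhappy", Kss >= 0) or tightly bound ("happy", Kss < 0), and
writes the ranked table under results/.
"""

import argparse
from pathlib import Path

from fwsolv.hydration import load_reference_sites, score_table

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    argparse.ArgumentParser(description=__doc__).parse_args()
    ref = load_reference_sites()
    scored = score_table(ref)

    RESULTS.mkdir(exist_ok=True)
    out = RESULTS / "hydration_sites_scored.csv"
    scored.drop(columns=["kss_score"]).to_csv(out, index=False)

    n_unhappy = int((scored.favorability == "unfavorable").sum())
    print(f"scored {len(scored)} hydration sites on the apo PD-L1 surface")
    print(f"  {n_unhappy} displaceable (Kss >= 0), {len(scored) - n_unhappy} tightly bound")
    top = scored.iloc[0]
    bottom = scored.iloc[-1]
    print(
        f"  most displaceable: {top.site_id} (Kss {top.kss:+.2f}, dG {top.delta_g:+.2f} kcal/mol)"
    )
    print(
        f"  most tightly bound: {bottom.site_id} (Kss {bottom.kss:+.2f}, dG {bottom.delta_g:+.2f} kcal/mol)"
    )
    print(f"  wrote {out}")


if __name__ == "__main__":
    main()
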