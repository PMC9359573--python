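#!/usr/bin/env python
"""In-silico evaluation of the RTkdr oligo set against Vgsc templates.

Uses the bundled synthetic templates (which embed the real primer/probe
sites with the published geometry): locates binding sites, extracts the
sequencing RT-PCR product, counts probe mismatches per template, measures
cross-template amplicon identity, and reads the 1014 genotype off each
product. Writes results/assay_eval.csv.
"""

from pathlib import Path

import pandas as pd

from culexkdr import assay, synthetic

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    oligos = assay.default_oligos()
    templates = synthetic.synthetic_vgsc_templates()

    rows = []
    amplicons = {}
    for t in templates.values():
        pcr = assay.in_silico_pcr(t, oligos["RTSeq_Fwd"], oligos["RTkdr_Rev"])
        if pcr.status != "ok":
            rows.append({"template": t.id, "status": pcr.status})
            continue
        amp = pcr.amplicon
        amplicons[t.id] = amp
        rows.append(
            {
                "template": t.id,
                "status": "ok",
                "product_bp": amp.length,
                "fwd_mismatches": amp.fwd_mismatches,
                "rev_mismatches": amp.rev_mismatches,
                "probe_TTA_mismatches": assay.probe_mismatch_count(amp, oligos["RTkdr_TTA"]),
                "probe_TTT_mismatches": assay.probe_mismatch_count(amp, oligos["RTkdr_TTT"]),
                "genotype_at_1014": assay.genotype_from_sequence(amp),
            }
        )

    ref = amplicons["tarsalis_syn"]
    for row in rows:
        if row["status"] == "ok":
            row["identity_vs_reference_pct"] = round(
                assay.percent_identity(amplicons[row["template"]].bases, ref.bases), 2
            )

    df = pd.DataFrame(rows)
    df.to_csv(OUT / "assay_eval.csv", index=False)
    print(df.to_string(index=False))
    print(f"\nThe sequencing primer pair yields a {ref.length} bp product; the "
          f"sister template is {df.set_index('template').loc['erythrothorax_syn', 'identity_vs_reference_pct']:.0f}% "
          f"identical across it, while the divergent template carries "
          f"{df.set_index('template').loc['pipiens_syn', 'probe_TTA_mismatches']} probe mismatches "
          f"yet amplifies with perfect primer matches.")
    print(f"wrote {OUT / 'assay_eval.csv'}")


if __name__ == "__main__":
    main()
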