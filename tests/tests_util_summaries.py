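"""Shared helper: synthetic epoch summaries with prescribed extinction counts."""

from stcsim.evolution import EpochSummary


def make_summaries_with_ells(ells):
    out = []
    Z = 0
    L = 100
    for i, ell in enumerate(ells):
        Z += 1
        L += 1 - int(ell)
        out.append(
            EpochSummary(
                T=i + 1,
                L=L,
                Z=Z,
                invader_succeeded=True,
                ell=int(ell),
                s_hat=0.0,
                L_eff=float(L),
                upsilon_bar=0.0,
                epoch_duration=1.0,
            )
        )
    return out
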