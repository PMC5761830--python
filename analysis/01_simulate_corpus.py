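"""Generate the study-shaped synthetic corpus the downstream analyses consume.

25 breeding pairs, 1-5 48-h observation sessions each (median 3) spread over
two breeding years, short/long foraging-trip mixture with moderate pair
coordination (kappa = 0.6), one chick per pair-year.  Writes the corpus CSVs
plus generator ground truth under results/corpus/.
"""

from pathlib import Path

from dualforage import SimParams, simulate_corpus

OUT = Path(__file__).resolve().parent.parent / "results" / "corpus"


def main(seed: int = 0) -> None:
    params = SimParams(seed=seed)
    corpus = simulate_corpus(params, out_dir=OUT)
    n_sessions = len(corpus.truths)
    n_trips = sum(len(t.trips) for t in corpus.truths)
    print(f"corpus: {params.n_pairs} pairs, {n_sessions} sessions, "
          f"{n_trips} true trips, {len(corpus.chick_truths)} chicks -> {OUT}")


if __name__ == "__main__":
    main()
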