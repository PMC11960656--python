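"""Ancestral tool-use probabilities under the threshold model.

A latent liability evolves along the tree as a stationary
Ornstein-Uhlenbeck process; a node is a tool user when its liability is
positive. Tip states come from three codings: hard "pre" (literature
evidence only), hard "post" (union of channels), and the soft "cure"
coding that feeds the survival-cure model's posterior tool-use
probabilities in as tip-state probabilities. The synthetic dataset has a
single genus, so the genus MRCA table reduces to the tree root: the
reported probability is the pooled posterior probability that the common
ancestor of all sampled species was a tool user.

Writes the MRCA table to results/asr/.
"""

import argparse
import pathlib

from phylocure.asr import AsrConfig, genus_mrca_table
from phylocure.data import load_traits
from phylocure.inference import PosteriorDraws, rank_species
from phylocure.phylo import load_trees

ROOT = pathlib.Path(__file__).resolve().parent.parent


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=20242)
    ap.add_argument("--data", type=pathlib.Path, default=ROOT / "results" / "data")
    ap.add_argument("--fit", type=pathlib.Path, default=ROOT / "results" / "fit")
    ap.add_argument("--out", type=pathlib.Path, default=ROOT / "results" / "asr")
    ap.add_argument("--n-iter", type=int, default=20_000)
    ap.add_argument("--n-trees", type=int, default=3)
    args = ap.parse_args()

    ensemble = load_trees(args.data / "trees.nwk")
    dataset = load_traits(
        args.data / "traits.csv", tree_tip_labels=set(ensemble.tip_labels)
    ).subset_in_tree()

    codings = {
        "pre": {r.species_id: float(r.literature.detected) for r in dataset},
        "post": {r.species_id: float(r.any_evidence) for r in dataset},
    }
    draws_path = args.fit / "draws.csv"
    if draws_path.exists():
        draws = PosteriorDraws.load(draws_path, args.fit / "draws_meta.json")
        medians = rank_species(draws).set_index("species")["median"]
        codings["cure"] = {s: float(medians[s]) for s in dataset.species_ids}
    else:
        print(f"note: {draws_path} missing; run 02_fit_model.py for the "
              "soft 'cure' coding")

    genera = sorted({s.split()[0] for s in dataset.species_ids})
    table = genus_mrca_table(
        ensemble,
        codings,
        genera,
        AsrConfig(n_iter=args.n_iter),
        seed=args.seed,
        n_trees=args.n_trees,
    )
    args.out.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out / "mrca_table.csv", index=False)
    print(f"wrote {args.out}/mrca_table.csv")
    print(table.to_string(index=False))


if __name__ == "__main__":
    main()
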