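"""Local alignment and e-value search with the built-in engine.

The engine is an affine-gap Smith-Waterman (BLOSUM62, gap open -11 / extend
-1) with Karlin-Altschul statistics (E = K*m*n*exp(-lambda*S)); it is
interchangeable with externally supplied 12-column tabular hits in the
enzyme-classification stages.
"""
from secretome_profiler import ProteinRecord, estimate_evalue, local_align, search

a = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
b = "MKTAYIAKQRQISFVKSHFSRQAPEERLGLIEVQ"
res = local_align(a, b)
print(f"score {res.raw_score:.0f}, bitscore {res.bitscore:.1f}, "
      f"query span {res.q_span}, subject span {res.s_span}")
print(res.aligned_query)
print(res.aligned_subject)

# an e-value is the expected number of chance hits at this score in an
# m x n search space: it grows linearly with the database size
print(f"\nE at score 50, m=n=100: {estimate_evalue(50.0, 100, 100):.3e}")
print(f"E at score 50, m=100, n=200: {estimate_evalue(50.0, 100, 200):.3e}")

queries = [ProteinRecord("query", "magA", a)]
db = [ProteinRecord("homolog", "db", b), ProteinRecord("unrelated", "db", "GGSGG" * 8)]
for hit in search(queries, db, evalue_cutoff=1e-5):
    print(f"\nhit: {hit.query_id} -> {hit.subject_id}  "
          f"pident={hit.percent_identity}  E={hit.evalue:.2e}")
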