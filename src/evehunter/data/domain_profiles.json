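{
 "RT_core": {
  "klass": "shared",
  "consensus": "LAGKSGAMEAPSKYMEDSVYDESQRAIRFSVLRKYFPKDSKLPQGKVLLCVLRGPLCVNDGDLHTPQEDATVYMPSEQMKDEYYIGMGYVDDPGALVEFDNIKLAADLPEGCGDTIRTALWSEDISADGFTHYQKAEVRR",
  "cutoff_frac": 0.35
 },
 "RNaseH": {
  "klass": "shared",
  "consensus": "EALLLFTDGSISASYALAFLDASGGTAIPPLKLTRDTRGSREEYPSHDAPKVLTFLGRDQPWELALHSQRIEFKIFIFDGASKYGCDTGPHVLGLPQRWS",
  "cutoff_frac": 0.35
 },
 "AP": {
  "klass": "caulimovirid_associated",
  "consensus": "NIIYDGGFNSVDLKEESRAFYDMEADTGALQMDAVARLRLDDLITFPNDVSVDVLGSVRLIIVPLLIVFEIGDNSMRLLN",
  "cutoff_frac": 0.35
 },
 "MP": {
  "klass": "caulimovirid_associated",
  "consensus": "ADTLSADRTGGAIMGTEMSTKGAESLLNEMSAWFEILKGGETEDQNVLVTGGNFNYWHDSPSKTDLKHNLVSGPAGKNFVAHEQDDLESRKGLAVKATQTERERKNEGNTGLISVGRQDP",
  "cutoff_frac": 0.35
 },
 "zf_CCHC": {
  "klass": "shared",
  "consensus": "LLRRVLPVCITCGSIGHGARVCGTMPRQNKKIGAANEKLP",
  "cutoff_frac": 0.35
 },
 "integrase": {
  "klass": "te_specific",
  "consensus": "LNLFGPPHDLHHCCVENFFSADQRFLNIPGREGQGRSQTNDMQVIAIFKDSNGVTETTSKHDALAHRTKGSNGEDDYPFLTSMILLDITEDSSDLVRGYSELTGVLKNVP",
  "cutoff_frac": 0.35
 },
 "transposase": {
  "klass": "te_specific",
  "consensus": "HIVRNYYGPRYTSALLLLQRGLTKSEAQFIRWPAELLPDLVIPTTAGPSKDDESPFLEDGDSVPGGSLKVIIPVEFIWEIAMRADLADIDYFPKWADTVK",
  "cutoff_frac": 0.35
 }
}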