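>P48678|PRELAMIN_A_MOUSE synthetic stand-in sequence (665 aa; printed surrogate peptides and processing junctions at published coordinates; filler elsewhere) deletion=608-657
AEGLQDSKTVSELNGRDSQTLAEKNVGSELTRAGDSQVLKSETNAGLRDLQSVAEKGTNS
ELVRAQDSGTLKSVNELAGRTDQSGVEKLNAGSETRAEGLQDSKTVSELNGRDSQTLAEK
NVGSELTRAGDSQVLKSETNAGLRDLQSVAEKGTNSELVRAQDSGTLKSVNELAGRTDQS
GVEKLNAGSETRAEGLQDSKTVSELNGRDSQTLAEKNVGSELTRAGDSQVLKSETNAGLR
DLQSVAEKGTNSELVRAQDSGTLKSVNELAGRTDQSGVEKLNAGSETRAEGLQDSKTVSE
LNGRDSQTLAEKNVGSELTRAGDSQVLKSETNAGLRDLQSVAEKGTNSELVRAQDSGTLK
SVNELAGRTDQSGVEKLNAGSETRAEGLQDSKTVSELNGRDSQTLAEKNVGSELTRAGDS
QVLKSETNAGLRDLQSVAEKGTNSELVRAQDSGTLKSVNELAGRTDQSGVEKLNAGSETR
AEGLQDSKTVSELNGRDSQTLAEKNVGSELTRAGDSQVLKSETNAGLRDLQSVAEKGTNS
ELVRAQDSGTLKSVNELAGRTDQSGVEKLNAGSETRADSGTNVELKTVLCGTCGQPADKA
AGGAGAQGSKTAQELSNVKSVGGSGGGSFGDNLVTRTPSGSAKSYLLGNSSPRTRSQSSQ
NCSIM
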