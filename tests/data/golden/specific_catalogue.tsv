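subject_id	v_gene	cdr3_aa	antigens	cross_reactive	filtered_by_baseline
S01	TCRBV18.01.01	CASSAATVVIPNF	G12V	False	False
S01	TCRBV20.01.01	CASSCEFHNNYCFF	G12R	False	False
S01	TCRBV30.01.01	CASSDDECDF	G12V	False	True
S01	TCRBV30.01.01	CASSDMMGIIKYREGF	G12C	False	False
S01	TCRBV14.01.01	CASSFGHPCAKF	G12C	False	False
S01	TCRBV18.01.01	CASSFGQHFPQSVKWRF	G13D	False	False
S01	TCRBV06.01.01	CASSFYWFYEF	G12D+G12V+G13D	True	False
S01	TCRBV10.01.01	CASSGGKPYKCF	G12V	False	False
S01	TCRBV20.01.01	CASSHSMESRVDEHF	G12A+G12R	True	False
S01	TCRBV09.01.01	CASSIFDHYNKF	G12C+G12D	True	False
S01	TCRBV14.01.01	CASSIFQMMKF	G12A+G12C+G12R	True	False
S01	TCRBV25.01.01	CASSIMRCQTWF	G12A+G12D	True	False
S01	TCRBV27.01.01	CASSKLEVEPGDNGRF	G12A	False	False
S01	TCRBV12.01.01	CASSMGHSIGPF	G12A	False	False
S01	TCRBV06.01.01	CASSMSAPCF	G13D	False	False
S01	TCRBV14.01.01	CASSNWPTWEREIF	G12V	False	True
S01	TCRBV09.01.01	CASSPWGEMF	G12A	False	False
S01	TCRBV14.01.01	CASSQLPLRF	G12D	False	False
S01	TCRBV12.01.01	CASSQSPTLSCHDF	G12C	False	False
S01	TCRBV07.01.01	CASSSNKMPGVKDICSKF	G13D	False	False
S01	TCRBV07.01.01	CASSVGRQIKLQEMDF	G13D	False	False
S01	TCRBV28.01.01	CASSWMLWTF	G12A	False	False
S01	TCRBV29.01.01	CASSYCPSCNFCCF	G12V	False	False
S01	TCRBV04.01.01	CASSYEQYMSYYKCF	G12R	False	False
S01	TCRBV11.01.01	CASSYTCHSKQKPMLLPF	G12R	False	True
S02	TCRBV18.01.01	CASSASFSCWF	G12A+G13D	True	False
S02	TCRBV29.01.01	CASSCAQWQFDQMF	G12A+G12V	True	False
S02	TCRBV15.01.01	CASSCFHQSFLMWGSGF	G12C	False	False
S02	TCRBV07.01.01	CASSCFYYLKGHRCVF	G12D	False	False
S02	TCRBV11.01.01	CASSCNAFFFRRCIF	G12R	False	False
S02	TCRBV06.01.01	CASSCQPDPRTWKF	G12A	False	False
S02	TCRBV14.01.01	CASSEAVYTQMKAIGIYF	G13D	False	True
S02	TCRBV02.01.01	CASSEFCVSTGRMF	G12R	False	False
S02	TCRBV02.01.01	CASSGPQAILF	G12A	False	False
S02	TCRBV11.01.01	CASSICLFYCLSVAF	G12A+G12C	True	False
S02	TCRBV25.01.01	CASSIKASWHIMDCDCDF	G12R	False	False
S02	TCRBV20.01.01	CASSLNVIEVFEF	G12D	False	True
S02	TCRBV02.01.01	CASSMKCPQMSLCRF	G12V	False	False
S02	TCRBV02.01.01	CASSNPCQRANCVMKF	G12A	False	False
S02	TCRBV07.01.01	CASSPEYWDQQHNHNF	G12D+G12V	True	False
S02	TCRBV11.01.01	CASSPSEQHFHYQNNTEF	G12D	False	False
S02	TCRBV28.01.01	CASSQQSAQKGAVCMFEF	G12R	False	False
S02	TCRBV05.01.01	CASSRTCLKPEKTYF	G12A	False	False
S02	TCRBV12.01.01	CASSSHSLFRCWAIF	G12A	False	False
S02	TCRBV20.01.01	CASSSRKWFFLKGWHF	G13D	False	False
S02	TCRBV10.01.01	CASSTFPFGFF	G12V	False	True
S02	TCRBV24.01.01	CASSTIFEHRF	G12C+G12V	True	False
S02	TCRBV04.01.01	CASSTRTGFF	G12C+G13D	True	False
S02	TCRBV10.01.01	CASSVMRSWIWKDF	G12V	False	False
S02	TCRBV11.01.01	CASSVNEQFMIF	G12A+G12C+G12R	True	False
S03	TCRBV24.01.01	CASSCYNFNWF	G12R	False	False
S03	TCRBV19.01.01	CASSDVRMFYHTCQF	G13D	False	True
S03	TCRBV12.01.01	CASSDYGRWLGCF	G12C+G13D	True	False
S03	TCRBV29.01.01	CASSFLPDKWF	G13D	False	False
S03	TCRBV19.01.01	CASSFWWNSSSAMF	G12D	False	False
S03	TCRBV12.01.01	CASSGVDTCF	G12C	False	True
S03	TCRBV30.01.01	CASSHNWQHHIHQGCGAF	G12A	False	False
S03	TCRBV14.01.01	CASSIVVHHENF	G12C+G12V	True	False
S03	TCRBV27.01.01	CASSKHHATKFNF	G12D	False	False
S03	TCRBV11.01.01	CASSKNFEVAEANEDKHF	G12A	False	False
S03	TCRBV20.01.01	CASSKRMWGAYGCF	G12R	False	False
S03	TCRBV29.01.01	CASSMQSGDEF	G12D	False	False
S03	TCRBV27.01.01	CASSMRFDWSSLSSDCF	G13D	False	False
S03	TCRBV09.01.01	CASSNRICQHFF	G12V	False	False
S03	TCRBV20.01.01	CASSPNLPFGNEF	G12A	False	False
S03	TCRBV15.01.01	CASSPWIWPFF	G12V	False	False
S03	TCRBV04.01.01	CASSQFLVKWF	G12C	False	True
S03	TCRBV29.01.01	CASSRDIERKKNAF	G12R	False	False
S03	TCRBV29.01.01	CASSRGKTMWQF	G12C	False	False
S03	TCRBV05.01.01	CASSRTCLKPEKTYF	G12A	False	False
S03	TCRBV29.01.01	CASSTLETHNFGCYCF	G12R	False	False
S03	TCRBV24.01.01	CASSWDGGIKIMNESDSF	G12C	False	False
S03	TCRBV19.01.01	CASSWNNIQYSLMNIF	G12A	False	False
S03	TCRBV20.01.01	CASSWRNQAFQPDF	G12V	False	False
S03	TCRBV15.01.01	CASSWWHDYF	G12D+G12V	True	False
S03	TCRBV29.01.01	CASSYCPSCNFCCF	G12V	False	False
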