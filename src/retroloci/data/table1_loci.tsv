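name	class	gag	pol	env	ORF1	ORF2	aliases
Chr1 69.5M	ERV		chr1:69699445-69702763 (-)
Chr1 182.3M	ERV	chr1:182258186-182259898 (+)	chr1:182259902-182263444 (+)	chr1:182263297-182265366 (+)
Chr2 16M	ERV	chr2:16026714-16028352 (-)	chr2:16023111-16026710 (-)	chr2:16021273-16023315 (-)
Chr2 24.2M	ERV	chr2:24193743-24195578 (+)	chr2:24195434-24197905 (+)
Chr5 110M	ERV	chr5:109905189-109906993 (-)	chr5:109901775-109905185 (-)
Chr5 23.7M	ERV	chr5:23706608-23708539 (-)	chr5:23703026-23706604 (-)	chr5:23701149-23703218 (-)			Xmv45
Chr5 24.2M	ERV	chr5:24216220-24217932 (+)	chr5:24217932-24219533 (+)	chr5:24219518-24221581 (+)
Chr5 25.2M	ERV	chr5:25231883-25233520 (+)	chr5:25233524-25236934 (+)	chr5:25236919-25238892 (+)			Mpmv13
Chr6 73.3M	ERV	chr6:73291329-73292966 (-)	chr6:73287915-73290254 (-)
Chr7 29.6M	ERV	chr7:29616273-29617985 (+)	chr7:29617989-29621588 (+)	chr7:29621384-29623171 (+)
Chr7 30.6M	ERV	chr7:30689706-30691418 (+)	chr7:30691422-30694964 (+)	chr7:30694817-30696886 (+)			Pmv15
Chr8 123.2M	ERV	chr8:123165736-123167538 (+)	chr8:123167542-123171295 (+)
Chr8 123.4M	ERV	chr8:123431904-123433835 (-)	chr8:123428313-123431900 (-)	chr8:123426364-123428661 (-)			Emv2
Chr8 85.1M	ERV	chr8:85129579-85131291 (-)	chr8:85126740-85129583 (-)	chr8:85126466-85126753 (-)
Chr9 62.4M	ERV	chr9:62440115-62441827 (+)	chr9:62441827-62445417 (+)	chr9:62445225-62447282 (+)
Chr11 88.9M	ERV	chr11:88894192-88895901 (-)	chr11:88892779-88894188 (-)	chr11:88890914-88892971 (-)
Chr13 21.8M	ERV	chr13:21813594-21815231 (+)	chr13:21815235-21818834 (+)
Chr13 99M	ERV	chr13:98992477-98994189 (-)	chr13:98988931-98992473 (-)	chr13:98987009-98989078 (-)
Chr16 36.3M	ERV		chr16:36327413-36330097 (+)
Chr16 93.7M	ERV	chr16:93703659-93705161 (-)	chr16:93700056-93703655 (-)	chr16:93698191-93700260 (-)
Chr18 82.7M	ERV	chr18:82694617-82696228 (+)	chr18:82696232-82699831 (+)	chr18:82699627-82701696 (+)			Pmv20
Chr19 38.4M	ERV	chr19:38376901-38377800 (+)	chr19:38377804-38381094 (+)
ChrY 4.8M	ERV	chrY:4801494-4802729 (-)	chrY:4797903-4801490 (-)	chrY:4796026-4798095 (-)
Chr3 5.9M	LINE1					chr3:5860754-5862853 (+)
Chr3 18.3M	LINE1					chr3:18293034-18293999 (-)
Chr13 34.6M	LINE1					chr13:34614319-34616805 (+)
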